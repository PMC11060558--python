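"""Baseline-rate measurement and bisection weight calibration.

Synaptic weights are tuned per connection type by bisecting a scalar
multiplier on the type's weights until the simulated no-stimulus baseline
rate of the postsynaptic population matches its target.  The search assumes
the rate is monotone in the multiplier (increasing for excitatory types,
decreasing for inhibitory ones); a non-bracketing initial interval aborts
with a diagnostic listing the sampled rate-vs-multiplier pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import SimulationEngine
from .plasticity import PlasticityRuleParams
from .protocol import LesionConfig, make_engine
from .scaffold import Network

__all__ = ["baseline_rates", "calibrate_weights", "CalibrationReport"]


def baseline_rates(
    engine: SimulationEngine,
    duration_ms: int = 5000,
    rng: np.random.Generator | None = None,
    background_rate_hz: float = 1.0,
    split_pc_modules: bool = True,
) -> dict[str, float]:
    """Mean per-capita firing rates (Hz) in a no-stimulus run.

    Mossy fibres carry only the 1 Hz background.  PC rates are reported per
    micromodule (``PC_down`` / ``PC_up``) when requested.
    """
    r = rng if rng is not None else np.random.default_rng(0)
    mf = r.random((engine.n["mf"], duration_ms)) < background_rate_hz / 1000.0
    engine.reset_trial_state(randomize=True, rng=r)
    rec = engine.run_trial(mf.astype(float))
    out = {}
    for pop in engine.recorded:
        ids, ts = rec.of(pop)
        n = engine.n[pop]
        if pop == "PC" and split_pc_modules:
            down = engine.module_mask["PC"]
            nd = int(down.sum())
            cd = int(down[ids].sum())
            out["PC_down"] = cd / nd / (duration_ms / 1000.0) if nd else 0.0
            out["PC_up"] = (ids.size - cd) / max(n - nd, 1) / (duration_ms / 1000.0)
        out[pop] = ids.size / n / (duration_ms / 1000.0) if n else 0.0
    return out


@dataclass
class CalibrationReport:
    """Outcome of one connection type's bisection."""

    type_name: str
    multiplier: float
    achieved_rate: float
    target_rate: float
    converged: bool
    iterations: int
    samples: list[tuple[float, float]]   # (multiplier, rate) pairs probed


def calibrate_weights(
    network: Network,
    target_baseline_rates: dict[str, float],
    tolerance_hz: float = 2.0,
    types: list[str] | None = None,
    duration_ms: int = 3000,
    max_iter: int = 12,
    bracket: tuple[float, float] = (0.0, 4.0),
    plasticity: PlasticityRuleParams | None = None,
    seed: int = 0,
) -> tuple[dict[str, float], list[CalibrationReport]]:
    """Bisection search of per-type weight multipliers.

    ``target_baseline_rates`` maps a rate key (population name, or
    ``PC_down`` / ``PC_up``) to its target in Hz; ``types`` lists the
    connection types to tune, each judged against the target of its
    postsynaptic population.  Returns (multipliers, reports).  Types whose
    baseline is already within tolerance keep multiplier 1.0 with zero
    iterations.
    """
    if any(v <= 0 for v in target_baseline_rates.values()):
        raise ValueError("target rates must be positive")
    pl = plasticity or PlasticityRuleParams()

    def fresh_engine(mults: dict[str, float]) -> SimulationEngine:
        eng = make_engine(network, LesionConfig("control"), pl,
                          np.random.default_rng(seed),
                          plasticity_enabled=False)
        if mults:
            eng.scale_weights(mults)
        return eng

    def rate_key(post_pop: str) -> str:
        return post_pop if post_pop in target_baseline_rates else post_pop

    multipliers: dict[str, float] = {}
    reports: list[CalibrationReport] = []
    specs = {s.name: s for s in (network.specs or [])}
    if types is None:
        types = [n for n in specs if n != "mf_glom"]

    for name in types:
        spec = specs[name]
        key = rate_key(spec.post_population)
        if key not in target_baseline_rates:
            continue
        target = target_baseline_rates[key]
        inhibitory = spec.synapse_weight < 0

        def rate_at(m: float) -> float:
            eng = fresh_engine({**multipliers, name: m})
            rr = baseline_rates(eng, duration_ms, np.random.default_rng(seed))
            return rr[key]

        samples = []
        r1 = rate_at(1.0)
        samples.append((1.0, r1))
        if abs(r1 - target) <= tolerance_hz:
            multipliers[name] = 1.0
            reports.append(CalibrationReport(name, 1.0, r1, target, True, 0,
                                             samples))
            continue
        lo, hi = bracket
        r_lo = rate_at(lo)
        r_hi = rate_at(hi)
        samples += [(lo, r_lo), (hi, r_hi)]
        sign = -1.0 if inhibitory else 1.0
        if not (min(r_lo, r_hi) - tolerance_hz <= target <= max(r_lo, r_hi)
                + tolerance_hz):
            reports.append(CalibrationReport(name, 1.0, r1, target, False, 0,
                                             samples))
            raise ValueError(
                f"{name}: target {target} Hz not bracketed by multipliers "
                f"{bracket}; sampled rate-vs-weight pairs: {samples}")
        it = 0
        m_mid, r_mid = 1.0, r1
        while it < max_iter:
            m_mid = 0.5 * (lo + hi)
            r_mid = rate_at(m_mid)
            samples.append((m_mid, r_mid))
            if abs(r_mid - target) <= tolerance_hz:
                break
            # rate increases with multiplier for excitatory, decreases for
            # inhibitory types
            if (r_mid < target) == (sign > 0):
                lo = m_mid
            else:
                hi = m_mid
            it += 1
        multipliers[name] = m_mid
        reports.append(CalibrationReport(
            name, m_mid, r_mid, target, abs(r_mid - target) <= tolerance_hz,
            it + 1, samples))
    return multipliers, reports
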
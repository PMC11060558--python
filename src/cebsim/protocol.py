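"""Classical eyeblink conditioning (CEBC) protocol: stimuli, trials, lesions.

A trial is a 1-ms-grid window of ``baseline + CS + post`` milliseconds
(500 + 260 + 500 = 1260 by default):

* CS — a 10 Hz Poisson spike pattern on the central subset of mossy fibres
  (scaled from 45 of 117) for the CS duration, superimposed on a 1 Hz
  background that all mossy fibres receive throughout the trial.
* US — a 500 Hz burst lasting 10 ms, co-terminating with the CS, delivered
  to every inferior-olive neuron of the downbound micromodule (ISI = time
  from CS onset to US onset, default 250 ms).
* CIO — the conditioned IO response: a 400 Hz burst delivered to a fixed
  random half of downbound IO neurons at 88 ms after CS onset, with
  occurrence probability rising linearly over trials up to 0.43 at the end
  of learning.

Lesions emulate the mutant-mouse preparations: ``ltd_ko`` silences pf-PC
depression, ``mli_ko`` disconnects MLI output (SC-PC/BC-PC weights zero),
``double_ko`` applies both.

An experiment is ``n_seeds`` independent runs of ``n_blocks`` x
``trials_per_block`` trials with online plasticity; spikes, per-block
weight snapshots and per-trial raw motor traces are collected for analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .engine import SimulationEngine, TrialRecord
from .plasticity import PlasticityRuleParams, plasticity_gate
from .scaffold import (Network, NetworkConfig, assign_mli_preference,
                       build_network, default_connection_specs,
                       generate_connectivity)

__all__ = [
    "ProtocolConfig",
    "LesionConfig",
    "ExperimentResult",
    "generate_cs",
    "generate_us",
    "schedule_cio",
    "run_trial",
    "run_experiment",
    "build_default_network",
]


@dataclass(frozen=True)
class ProtocolConfig:
    """Timing and rates of the CEBC protocol (all times ms, rates Hz)."""

    baseline_ms: int = 500
    cs_duration_ms: int = 260
    cs_rate_hz: float = 10.0
    us_duration_ms: int = 10
    us_rate_hz: float = 500.0
    isi_ms: int = 250
    post_ms: int = 500
    cio_rate_hz: float = 400.0
    cio_duration_ms: int = 10
    cio_latency_ms: int = 88
    cio_max_probability: float = 0.43
    cio_fraction: float = 0.5
    background_rate_hz: float = 1.0
    n_blocks: int = 10
    trials_per_block: int = 100
    n_seeds: int = 3

    def __post_init__(self) -> None:
        if self.isi_ms + self.us_duration_ms != self.cs_duration_ms:
            raise ValueError(
                "US must co-terminate with CS: "
                "isi_ms + us_duration_ms must equal cs_duration_ms")
        if self.cio_latency_ms >= self.isi_ms:
            raise ValueError("CIO latency must precede US onset (ISI)")
        if not (0.0 <= self.cio_max_probability <= 1.0):
            raise ValueError("cio_max_probability must be in [0, 1]")
        if not (0.0 < self.cio_fraction <= 1.0):
            raise ValueError("cio_fraction must be in (0, 1]")

    @property
    def cs_onset(self) -> int:
        return self.baseline_ms

    @property
    def us_onset(self) -> int:
        return self.baseline_ms + self.isi_ms

    @property
    def trial_length(self) -> int:
        return self.baseline_ms + self.cs_duration_ms + self.post_ms

    @property
    def cr_window(self) -> tuple[int, int]:
        """Last 200 ms of the ISI (first 50 ms excluded at ISI 250)."""
        return (self.cs_onset + self.isi_ms - 200, self.cs_onset + self.isi_ms)

    @property
    def total_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def with_isi(self, isi_ms: int) -> "ProtocolConfig":
        """ISI variant (200 / 250 / 300 ms); CS still co-terminates with US."""
        return replace(self, isi_ms=isi_ms,
                       cs_duration_ms=isi_ms + self.us_duration_ms)


@dataclass(frozen=True)
class LesionConfig:
    """Knock-out configuration: control, ltd_ko, mli_ko or double_ko."""

    id: str = "control"

    def __post_init__(self) -> None:
        from .plasticity import LESION_IDS
        if self.id not in LESION_IDS:
            raise ValueError(f"unknown lesion id {self.id!r}")


# ---------------------------------------------------------------------------
def generate_cs(
    config: ProtocolConfig,
    rng: np.random.Generator,
    cs_mf_mask: np.ndarray,
) -> np.ndarray:
    """Mossy-fibre input of one trial: 1 Hz Poisson background on all mfs
    plus 10 Hz Poisson on the CS-target subset during the CS window.

    Returns a bool array (n_mf, trial_length).
    """
    n_mf = cs_mf_mask.size
    T = config.trial_length
    p_bg = config.background_rate_hz / 1000.0
    trains = rng.random((n_mf, T)) < p_bg
    if config.cs_rate_hz > 0:
        on, off = config.cs_onset, config.cs_onset + config.cs_duration_ms
        p_cs = config.cs_rate_hz / 1000.0
        cs = rng.random((int(cs_mf_mask.sum()), off - on)) < p_cs
        trains[cs_mf_mask, on:off] |= cs
    return trains


def generate_us(config: ProtocolConfig, io_down_mask: np.ndarray) -> np.ndarray:
    """US input of one trial: a regular ``us_rate_hz`` burst lasting
    ``us_duration_ms``, co-terminating with the CS, to every downbound IO
    neuron.  Returns a bool array (n_IO, trial_length)."""
    T = config.trial_length
    out = np.zeros((io_down_mask.size, T), dtype=bool)
    step = 1000.0 / config.us_rate_hz
    times = (config.us_onset
             + np.floor(np.arange(0, config.us_duration_ms - 1e-9, step))
             ).astype(int)
    out[np.ix_(io_down_mask, times)] = True
    return out


def cio_probability(trial_index: int, total_trials: int,
                    config: ProtocolConfig) -> float:
    """Linear per-trial ramp of the conditioned-IO occurrence probability,
    reaching ``cio_max_probability`` on the final trial."""
    if not (0 <= trial_index < total_trials):
        raise ValueError("trial_index out of range")
    return config.cio_max_probability * (trial_index + 1) / total_trials


def schedule_cio(
    trial_index: int,
    total_trials: int,
    config: ProtocolConfig,
    rng: np.random.Generator,
    cio_target_mask: np.ndarray,
) -> np.ndarray | None:
    """Optional conditioned-IO burst for this trial.

    Occurrence probability ramps linearly with the trial number,
    p = p_max * (trial_index + 1) / total_trials.  When drawn, a
    ``cio_rate_hz`` burst of ``cio_duration_ms`` starts ``cio_latency_ms``
    after CS onset on the fixed CIO target subset (half of downbound IO,
    drawn once per experiment)."""
    p = cio_probability(trial_index, total_trials, config)
    if rng.random() >= p:
        return None
    T = config.trial_length
    out = np.zeros((cio_target_mask.size, T), dtype=bool)
    step = 1000.0 / config.cio_rate_hz
    times = (config.cs_onset + config.cio_latency_ms
             + np.floor(np.arange(0, config.cio_duration_ms - 1e-9, step))
             ).astype(int)
    out[np.ix_(cio_target_mask, times)] = True
    return out


def draw_cio_targets(
    io_down_mask: np.ndarray,
    fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fixed random CIO-target subset: ``fraction`` of downbound IO cells."""
    down_idx = np.flatnonzero(io_down_mask)
    k = max(1, int(round(fraction * down_idx.size)))
    chosen = rng.choice(down_idx, size=k, replace=False)
    mask = np.zeros_like(io_down_mask)
    mask[chosen] = True
    return mask


# ---------------------------------------------------------------------------
@dataclass
class ExperimentResult:
    """Everything an analysis needs from one lesion condition."""

    protocol: ProtocolConfig
    lesion: LesionConfig
    network_config: NetworkConfig
    # per seed: list over trials of TrialRecord
    trials: list[list[TrialRecord]] = field(default_factory=list)
    # per seed: list over trials of bool (CIO delivered)
    cio_delivered: list[np.ndarray] = field(default_factory=list)
    # per seed: {type: (n_blocks+1, n_syn) weight snapshots, [0] = initial}
    weight_snapshots: list[dict[str, np.ndarray]] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)
    n_dcn_down: int = 0
    n_dcn_up: int = 0

    def last_block_trials(self, seed_idx: int) -> list[TrialRecord]:
        per_block = self.protocol.trials_per_block
        return self.trials[seed_idx][-per_block:]

    def block_trials(self, seed_idx: int, block: int) -> list[TrialRecord]:
        per_block = self.protocol.trials_per_block
        return self.trials[seed_idx][block * per_block:(block + 1) * per_block]


def build_default_network(network_config: NetworkConfig,
                          weight_overrides: dict[str, float] | None = None
                          ) -> Network:
    """Build, wire and label the scaffold with the shipped connection table."""
    net = build_network(network_config)
    generate_connectivity(net, default_connection_specs(weight_overrides))
    assign_mli_preference(net)
    return net


def make_engine(
    network: Network,
    lesion: LesionConfig,
    plasticity: PlasticityRuleParams,
    rng: np.random.Generator,
    **kw,
) -> SimulationEngine:
    gated, mli_cut = plasticity_gate(lesion.id, plasticity)
    return SimulationEngine(network, plasticity=gated,
                            mli_output_disconnected=mli_cut, rng=rng, **kw)


def run_trial(
    engine: SimulationEngine,
    protocol: ProtocolConfig,
    trial_index: int,
    total_trials: int,
    rng: np.random.Generator,
    cio_target_mask: np.ndarray | None = None,
    deliver_us: bool = True,
) -> tuple[TrialRecord, bool]:
    """One CS-US(-CIO) trial on a live engine; returns (record, cio_flag)."""
    io_down = engine.module_mask["IO"]
    mf_trains = generate_cs(protocol, rng, engine.cs_mf_mask)
    io_input = generate_us(protocol, io_down) if deliver_us else \
        np.zeros((io_down.size, protocol.trial_length), dtype=bool)
    cio = None
    if cio_target_mask is not None:
        cio = schedule_cio(trial_index, total_trials, protocol, rng,
                           cio_target_mask)
        if cio is not None:
            io_input |= cio
    rec = engine.run_trial(mf_trains, io_input=io_input)
    return rec, cio is not None


def settle_engine(engine: SimulationEngine, protocol: ProtocolConfig,
                  rng: np.random.Generator, duration_ms: int = 500) -> None:
    """Warm up the network state with background input only.

    Membrane potentials are randomized and conductances run to their
    stationary regime so the first recorded trial starts from a settled
    state; thereafter state carries over from trial to trial (trials are
    contiguous stretches of simulated time), so no further reset is needed.
    """
    engine.reset_trial_state(randomize=True, rng=rng)
    p_bg = protocol.background_rate_hz / 1000.0
    mf = rng.random((engine.n["mf"], duration_ms)) < p_bg
    was_on = engine.plasticity_enabled
    engine.plasticity_enabled = False
    engine.run_trial(mf.astype(float))
    engine.plasticity_enabled = was_on


def run_experiment(
    network: Network,
    protocol: ProtocolConfig,
    plasticity: PlasticityRuleParams,
    lesion: LesionConfig = LesionConfig("control"),
    master_seed: int = 1,
    progress: bool = False,
) -> ExperimentResult:
    """Full CEBC experiment: ``n_seeds`` independent runs of
    ``n_blocks x trials_per_block`` trials with online plasticity.

    Each seed gets independent stimulus/noise streams derived from the
    master seed; network construction randomness is independent of these
    (lesions and seeds never perturb the wiring).
    """
    res = ExperimentResult(protocol=protocol, lesion=lesion,
                           network_config=network.config)
    dcn_down = (network.neurons.set_index("id")
                .loc[network.population_ids("DCN_p"), "micromodule"]
                .to_numpy() == "downbound")
    res.n_dcn_down = int(dcn_down.sum())
    res.n_dcn_up = int((~dcn_down).sum())

    for s in range(protocol.n_seeds):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(master_seed), s, 0x5E]))
        engine = make_engine(network, lesion, plasticity, rng)
        cio_targets = draw_cio_targets(engine.module_mask["IO"],
                                       protocol.cio_fraction, rng)
        settle_engine(engine, protocol, rng)
        trials: list[TrialRecord] = []
        cio_flags = np.zeros(protocol.total_trials, dtype=bool)
        snaps = {nm: [w.copy()] for nm, w in engine.initial_weights().items()}
        for i in range(protocol.total_trials):
            rec, had_cio = run_trial(engine, protocol, i,
                                     protocol.total_trials, rng, cio_targets)
            trials.append(rec)
            cio_flags[i] = had_cio
            if (i + 1) % protocol.trials_per_block == 0:
                for nm, w in engine.plastic_weights().items():
                    snaps[nm].append(w)
                if progress:
                    print(f"  seed {s}: block {(i + 1) // protocol.trials_per_block}"
                          f"/{protocol.n_blocks}", flush=True)
        res.trials.append(trials)
        res.cio_delivered.append(cio_flags)
        res.weight_snapshots.append(
            {nm: np.stack(ws) for nm, ws in snaps.items()})
        res.seeds.append(s)
    return res
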
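"""Alpha-conductance synapses and climbing-fibre-supervised plasticity rules.

Two long-term plasticity sites, both supervised by the climbing fibre (cf,
the olivary teaching signal), with opposite sign conventions:

* parallel fibre -> Purkinje cell (pf-PC): a cf spike depresses (LTD) the
  synapses of pf inputs that were active shortly before it; pf activity
  without a coincident cf spike potentiates (LTP).
* parallel fibre -> molecular-layer interneuron (pf-MLI): sign-reversed —
  a cf spike potentiates synapses of recently active pfs, weighted by an
  alpha-shaped kernel K(t) = (t/tau) * e^(1 - t/tau) with rise time
  tau = 50 ms (peaking at the pf-cf lag that maximizes MLI recruitment in
  the inter-stimulus interval); a pf spike without coincident cf activity
  depresses by a fixed amount.

"Coincident" means the same 1-ms simulation step.  The pf-PC depression
kernel is a fallback (the original closed form is not redistributed here):
a constant-window integrator counting pf spikes in the 200 ms before the cf
spike.  Weights are clipped to [w_min, w_max].
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PlasticityRuleParams",
    "alpha_conductance",
    "mli_kernel",
    "pc_ltd_kernel",
    "pf_mli_update",
    "pf_pc_update",
    "plasticity_gate",
    "LESION_IDS",
]

LESION_IDS = ("control", "ltd_ko", "mli_ko", "double_ko")

#: truncation of the alpha kernel support, in units of tau (contribution
#: beyond 10*tau is < e*10*e^-10 ~ 1e-3 of the peak)
KERNEL_CUTOFF_TAUS = 10.0

#: fallback pf-PC depression window (ms before the cf spike)
PC_LTD_WINDOW_MS = 200.0

#: shipped learning-rate defaults (nS per event), produced by the
#: calibration recipe (scripts/calibrate_rates.py): rates are balanced so
#: the end-of-learning firing modulation of downbound PCs, MLIs and DCN_p
#: matches the reference values, then linearly rescaled to the reference
#: protocol length below (per-event rates trade off against the number of
#: teaching events, so total weight change is approximately rate x trials).
DEFAULT_LEARNING_RATES = {
    "LTP_PC": 1.2e-5,
    "LTD_PC": 6.0e-4,
    "LTP_MLI": 3.5e-4,
    "LTD_MLI": 1.5e-4,
}
#: protocol length (total trials) the default rates are calibrated for
REFERENCE_TOTAL_TRIALS = 250


def default_rule_params(total_trials: int | None = None) -> "PlasticityRuleParams":
    """Shipped plasticity rates, linearly rescaled to a protocol length.

    ``total_trials=None`` returns the reference calibration unchanged."""
    f = 1.0 if total_trials is None else REFERENCE_TOTAL_TRIALS / total_trials
    return PlasticityRuleParams(**{k: v * f
                                   for k, v in DEFAULT_LEARNING_RATES.items()})


@dataclass(frozen=True)
class PlasticityRuleParams:
    """Learning rates and kernel constants for both plastic sites.

    Rates are dimensionless weight changes per event (in units of nS, the
    same as synaptic weights).  ``tau`` is the pf-MLI kernel rise time.
    ``w_max_factor`` bounds each weight to [0, w_max_factor * w_initial].
    """

    LTP_PC: float = 0.0
    LTD_PC: float = 0.0
    LTP_MLI: float = 0.0
    LTD_MLI: float = 0.0
    tau: float = 50.0
    w_min: float = 0.0
    w_max_factor: float = 4.0

    def __post_init__(self) -> None:
        if min(self.LTP_PC, self.LTD_PC, self.LTP_MLI, self.LTD_MLI) < 0:
            raise ValueError("plasticity rates must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.w_min < 0:
            raise ValueError("w_min must be >= 0 for excitatory pf synapses")


def alpha_conductance(t_since_presyn_spike, weight: float, tau_syn: float):
    """Alpha-shaped conductance transient, peak ``weight`` at ``t = tau_syn``.

    g(t) = weight * (t/tau) * exp(1 - t/tau) for t >= 0.  Superposition over
    spikes is additive; negative lags raise.
    """
    t = np.asarray(t_since_presyn_spike, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since presynaptic spike must be >= 0")
    return weight * (t / tau_syn) * np.exp(1.0 - t / tau_syn)


def mli_kernel(t, tau: float = 50.0):
    """pf-MLI LTP kernel K(t) = (t/tau) e^(1-t/tau) for t >= 0, else 0.

    Unimodal, K(tau) = 1 at its single maximum; support truncated at
    ``KERNEL_CUTOFF_TAUS * tau`` in the online implementation.
    """
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0.0, (t / tau) * np.exp(1.0 - t / tau), 0.0)
    return out if out.ndim else float(out)


def pc_ltd_kernel(t, window: float = PC_LTD_WINDOW_MS):
    """Fallback pf-PC depression kernel: 1 on (0, window] ms before the cf
    spike, else 0 (constant-window eligibility integrator)."""
    t = np.asarray(t, dtype=float)
    out = np.where((t > 0.0) & (t <= window), 1.0, 0.0)
    return out if out.ndim else float(out)


def _check_sorted(name: str, t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise ValueError(f"{name} spike train must be sorted")
    return t


def pf_mli_update(
    pf_spike_times,
    cf_spike_times,
    params: PlasticityRuleParams,
) -> float:
    """Total weight change of one pf-MLI synapse over a pair of spike trains.

    At each cf spike at time t_cf: dW = +LTP_MLI * sum over pf spikes s < t_cf
    of K(t_cf - s) (discrete realization of the convolution integral).  Each
    pf spike with no cf spike in the same 1-ms step: dW = -LTD_MLI.  The
    returned value is unclipped; bounds are applied where the synapse's
    absolute weight is known (engine / apply_bounds).
    """
    pf = _check_sorted("pf", pf_spike_times)
    cf = _check_sorted("cf", cf_spike_times)
    cutoff = KERNEL_CUTOFF_TAUS * params.tau
    cf_set = set(np.round(cf).astype(int)) if cf.size else set()

    dw = 0.0
    for t_cf in cf:
        lags = t_cf - pf
        sel = (lags > 0) & (lags <= cutoff)
        dw += params.LTP_MLI * float(np.sum(mli_kernel(lags[sel], params.tau)))
    for t_pf in pf:
        if int(round(t_pf)) not in cf_set:
            dw -= params.LTD_MLI
    return dw


def pf_pc_update(
    pf_spike_times,
    cf_spike_times,
    params: PlasticityRuleParams,
) -> float:
    """Total weight change of one pf-PC synapse (mirror structure, sign
    reversed): cf spike -> dW = -LTD_PC * sum of pc_ltd_kernel over prior pf
    spikes; pf spike without coincident cf -> dW = +LTP_PC."""
    pf = _check_sorted("pf", pf_spike_times)
    cf = _check_sorted("cf", cf_spike_times)
    cf_set = set(np.round(cf).astype(int)) if cf.size else set()

    dw = 0.0
    for t_cf in cf:
        lags = t_cf - pf
        dw -= params.LTD_PC * float(np.sum(pc_ltd_kernel(lags)))
    for t_pf in pf:
        if int(round(t_pf)) not in cf_set:
            dw += params.LTP_PC
    return dw


def apply_bounds(w: np.ndarray, w_initial: np.ndarray,
                 params: PlasticityRuleParams) -> np.ndarray:
    """Clip weights to [w_min, w_max_factor * w_initial] elementwise."""
    return np.clip(w, params.w_min, params.w_max_factor * np.asarray(w_initial))


def plasticity_gate(lesion_id: str, params: PlasticityRuleParams
                    ) -> tuple[PlasticityRuleParams, bool]:
    """Apply a knock-out lesion to the rule set.

    Returns (gated params, mli_output_disconnected).  ``ltd_ko`` zeroes the
    pf-PC depression rate (LTD knock-out mutant); ``mli_ko`` leaves
    plasticity untouched but requests SC-PC/BC-PC disconnection (MLI output
    knock-out, handled by the protocol engine); ``double_ko`` does both.
    """
    if lesion_id not in LESION_IDS:
        raise ValueError(f"unknown lesion id {lesion_id!r}; expected one of {LESION_IDS}")
    mli_cut = lesion_id in ("mli_ko", "double_ko")
    if lesion_id in ("ltd_ko", "double_ko"):
        params = replace(params, LTD_PC=0.0)
    return params, mli_cut
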
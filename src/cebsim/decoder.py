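"""Motor decoding: DCN_p spiking -> analog eyelid signal -> CR detection.

The eyelid signal is a rate-based readout of the deep-nuclei projection
neurons: per-capita instantaneous rate of each micromodule's DCN_p
population (so the 70/30 module size split does not bias amplitude), a
20-ms moving average, convolution with a Gaussian window (25 ms width,
interpreted as the standard deviation — the convention used for all
analysis kernels here), then the *net* signal downbound - upbound.  Per
trial the pre-CS baseline mean is subtracted; the result is normalized by
the maximum amplitude (maximum eye closure) over all control-condition
trials, which is frozen and reused for knock-out runs.

A conditioned response (CR) is scored when the normalized signal reaches

    threshold = max(0.2, mean(baseline) + 2.5 * STD(baseline))

inside the CR window, the last 200 ms of the inter-stimulus interval (the
first 50 ms are excluded as non-associative).  The first crossing is the CR
onset latency; the peak latency is the argmax from onset to trial end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .engine import TrialRecord
from .protocol import ProtocolConfig

__all__ = [
    "MotorTrace",
    "CRResult",
    "decode_motor",
    "raw_net_signal",
    "compute_cr_threshold",
    "detect_cr",
    "learning_curve",
    "cr_percentage_per_block",
]

MOVING_AVERAGE_MS = 20
GAUSSIAN_WIDTH_MS = 25.0
CR_THRESHOLD_FLOOR = 0.2
CR_THRESHOLD_SD_FACTOR = 2.5


@dataclass
class MotorTrace:
    """Decoded eyelid signal of one trial on the 1-ms grid."""

    trial_index: int
    amplitude: np.ndarray       # normalized (control-max units)
    baseline_mean: float
    baseline_std: float

    @property
    def n_samples(self) -> int:
        return self.amplitude.size


@dataclass
class CRResult:
    """Thresholded conditioned-response verdict for one trial."""

    is_cr: bool
    threshold: float
    onset_latency_ms: float | None   # after CS onset
    peak_latency_ms: float | None    # after CS onset
    peak_amplitude: float | None


def _percapita_rate(ids: np.ndarray, ts: np.ndarray, mask: np.ndarray,
                    T: int) -> np.ndarray:
    """Per-capita instantaneous rate (Hz) of the masked subpopulation."""
    n = int(mask.sum())
    if n == 0:
        return np.zeros(T)
    sel = mask[ids]
    counts = np.bincount(ts[sel].astype(int), minlength=T)[:T]
    return counts * (1000.0 / n)


def raw_net_signal(
    trial: TrialRecord,
    dcn_down_mask: np.ndarray,
    protocol: ProtocolConfig,
) -> np.ndarray:
    """Unnormalized smoothed net signal (downbound - upbound DCN_p rate)."""
    T = protocol.trial_length
    ids, ts = trial.of("DCN_p")
    r_down = _percapita_rate(ids, ts, dcn_down_mask, T)
    r_up = _percapita_rate(ids, ts, ~dcn_down_mask, T)

    def smooth(r):
        # constant (zero) padding: trial edges bias toward zero instead of
        # amplifying a single synchronized edge bin
        r = uniform_filter1d(r, size=MOVING_AVERAGE_MS, mode="constant")
        return gaussian_filter1d(r, sigma=GAUSSIAN_WIDTH_MS, mode="constant")

    return smooth(r_down) - smooth(r_up)


def decode_motor(
    trial: TrialRecord,
    dcn_down_mask: np.ndarray,
    protocol: ProtocolConfig,
    control_max_amplitude: float,
    trial_index: int = 0,
) -> MotorTrace:
    """Full decoding pipeline for one trial.

    ``control_max_amplitude`` is the maximum baseline-subtracted net signal
    over all control trials (for KO runs it must come from the matching
    control experiment; passing a non-positive value raises).
    """
    if not control_max_amplitude > 0:
        raise ValueError(
            "control_max_amplitude must be positive; for knock-out runs it "
            "is taken from the control simulations")
    net = raw_net_signal(trial, dcn_down_mask, protocol)
    base = net[:protocol.baseline_ms]
    m = float(base.mean())
    amp = (net - m) / control_max_amplitude
    base_n = amp[:protocol.baseline_ms]
    return MotorTrace(trial_index=trial_index, amplitude=amp,
                      baseline_mean=float(base_n.mean()),
                      baseline_std=float(base_n.std()))


def control_max_amplitude(
    trials: list[TrialRecord],
    dcn_down_mask: np.ndarray,
    protocol: ProtocolConfig,
) -> float:
    """Maximum baseline-subtracted net amplitude over control trials."""
    mx = 0.0
    for tr in trials:
        net = raw_net_signal(tr, dcn_down_mask, protocol)
        net = net - net[:protocol.baseline_ms].mean()
        mx = max(mx, float(net.max()))
    return mx


def compute_cr_threshold(trace: MotorTrace) -> float:
    """max(0.2, baseline mean + 2.5 * baseline STD)."""
    return max(CR_THRESHOLD_FLOOR,
               trace.baseline_mean + CR_THRESHOLD_SD_FACTOR * trace.baseline_std)


def detect_cr(
    trace: MotorTrace,
    threshold: float,
    protocol: ProtocolConfig,
) -> CRResult:
    """Score one trial: CR iff the signal reaches threshold in the CR window."""
    lo, hi = protocol.cr_window
    amp = trace.amplitude
    win = amp[lo:hi]
    above = win >= threshold
    if not above.any():
        return CRResult(False, threshold, None, None, None)
    onset = lo + int(np.argmax(above))
    peak = onset + int(np.argmax(amp[onset:]))
    return CRResult(
        True, threshold,
        onset_latency_ms=float(onset - protocol.cs_onset),
        peak_latency_ms=float(peak - protocol.cs_onset),
        peak_amplitude=float(amp[peak]),
    )


def score_trials(
    trials: list[TrialRecord],
    dcn_down_mask: np.ndarray,
    protocol: ProtocolConfig,
    control_max: float,
) -> list[CRResult]:
    out = []
    for i, tr in enumerate(trials):
        trace = decode_motor(tr, dcn_down_mask, protocol, control_max, i)
        out.append(detect_cr(trace, compute_cr_threshold(trace), protocol))
    return out


def cr_percentage_per_block(cr_results: list[CRResult],
                            trials_per_block: int) -> np.ndarray:
    """%CR per consecutive block of trials."""
    n = len(cr_results)
    if n == 0 or n % trials_per_block:
        raise ValueError("results do not divide into whole blocks")
    flags = np.array([r.is_cr for r in cr_results], dtype=float)
    return flags.reshape(-1, trials_per_block).mean(axis=1) * 100.0


def learning_curve(
    per_seed_results: list[list[CRResult]],
    trials_per_block: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SD of %CR per block across seeds.

    Raises on empty input (a block with no trials is meaningless).
    """
    if not per_seed_results or not per_seed_results[0]:
        raise ValueError("no CR results")
    curves = np.stack([
        cr_percentage_per_block(r, trials_per_block) for r in per_seed_results
    ])
    return curves.mean(axis=0), curves.std(axis=0)
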
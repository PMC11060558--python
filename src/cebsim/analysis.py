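"""Spike-train analysis: SDF, spike sorting, modulation, plasticity curves.

The spike density function (SDF) estimates the instantaneous firing rate of
one trace (one cell in one trial) by convolving its spike times with a
normalized Gaussian kernel ("width" = standard deviation throughout this
package): 41 ms for MLI and Purkinje simple spikes, 10 ms for DCN_p, 5 ms
for Purkinje complex spikes and IO.

Purkinje complex spikes (PC-CS, the climbing-fibre-evoked bursts) are
separated from simple spikes (PC-SS): a maximal run of >= 2 spikes whose
inter-spike intervals all correspond to more than twice the baseline rate
is one complex spike, timestamped at its first spike and substituted by a
single spike in the SS series.

Firing modulation of a trace is the average percent SDF deviation from the
trace's baseline over the CR window, split into suppression (instants
strictly below baseline) and facilitation (strictly above; instants equal
to baseline belong to neither).  A trace is significantly modulated when
its CR-window deviation exceeds the deviation the same formula yields on
the baseline window itself.  Plasticity curves report, per block and site,
the mean percent weight change of synapses moving in each direction (LTD /
LTP) multiplied by the fraction of synapses moving that way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

__all__ = [
    "SDFTrace",
    "ModulationResult",
    "compute_sdf",
    "separate_ss_cs",
    "compute_modulation",
    "flag_significant",
    "recruitment",
    "plasticity_curves",
    "sdf_min_time_distribution",
    "cumulative_square_distance",
    "SDF_WIDTH_MS",
]

#: Gaussian kernel widths (standard deviation, ms) per signal class
SDF_WIDTH_MS = {"MLI": 41.0, "PC_SS": 41.0, "DCN_p": 10.0, "PC_CS": 5.0,
                "IO": 5.0}


@dataclass
class SDFTrace:
    """SDF of one cell in one trial, with its pre-CS baseline mean."""

    cell_id: int
    trial_index: int
    values: np.ndarray          # Hz, on the 1-ms grid
    baseline_mean: float        # mean SDF over the pre-CS window

    @property
    def normalized(self) -> np.ndarray:
        return self.values / self.baseline_mean


@dataclass
class ModulationResult:
    """Suppression / facilitation percentages of one trace's CR window."""

    suppression: float          # <= 0 (%)
    facilitation: float         # >= 0 (%)
    n_suppressed: int
    n_facilitated: int
    significant: bool = False
    valid: bool = True          # False when the baseline SDF is ~0


def compute_sdf(
    spike_times: np.ndarray,
    kernel_width: float,
    grid: np.ndarray,
    baseline_window: tuple[int, int] | None = None,
    cell_id: int = 0,
    trial_index: int = 0,
) -> SDFTrace:
    """Sum of normalized Gaussian densities centred on the spikes (Hz).

    The ms->s conversion makes a single spike contribute a peak of
    1000 / (width * sqrt(2 pi)) Hz at its own time.  Each grid point is
    renormalized by the kernel mass falling inside the recorded window
    (boundary-corrected kernel estimate), so the rate estimate is unbiased
    near the trial edges where part of the kernel support is unobserved.
    """
    if kernel_width <= 0:
        raise ValueError("kernel width must be > 0")
    t = np.asarray(spike_times, dtype=float)
    g = np.asarray(grid, dtype=float)
    if t.size:
        d = g[:, None] - t[None, :]
        vals = np.exp(-0.5 * (d / kernel_width) ** 2).sum(axis=1)
        vals *= 1000.0 / (kernel_width * np.sqrt(2.0 * np.pi))
        mass = 0.5 * (erf((g[-1] - g) / (kernel_width * np.sqrt(2.0)))
                      - erf((g[0] - g) / (kernel_width * np.sqrt(2.0))))
        vals /= np.maximum(mass, 1e-12)
    else:
        vals = np.zeros(g.size)
    base = 0.0
    if baseline_window is not None:
        lo, hi = baseline_window
        sel = (g >= lo) & (g < hi)
        base = float(vals[sel].mean()) if sel.any() else 0.0
    return SDFTrace(cell_id=cell_id, trial_index=trial_index,
                    values=vals, baseline_mean=base)


def separate_ss_cs(
    pc_spike_times: np.ndarray,
    baseline_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Split a Purkinje train into (simple spikes, complex-spike times).

    A complex spike is a maximal run of >= 2 spikes whose consecutive ISIs
    are all shorter than 1000 / (2 * baseline_rate) ms, i.e. instantaneous
    frequency more than twice baseline.  The run is replaced by one spike
    (its first time) in the SS series.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline rate must be > 0")
    t = np.asarray(pc_spike_times, dtype=float)
    if t.size == 0:
        return t.copy(), np.empty(0)
    cutoff = 1000.0 / (2.0 * baseline_rate)
    isi = np.diff(t)
    fast = isi < cutoff
    ss, cs = [], []
    i = 0
    n = t.size
    while i < n:
        j = i
        while j < n - 1 and fast[j]:
            j += 1
        if j > i:           # run of j-i+1 >= 2 spikes at > 2x baseline
            cs.append(t[i])
            ss.append(t[i])  # substituted by a single spike in the SS series
        else:
            ss.append(t[i])
        i = j + 1
    return np.array(ss), np.array(cs)


def compute_modulation(
    sdf: SDFTrace,
    cr_window: tuple[int, int],
    grid: np.ndarray | None = None,
) -> ModulationResult:
    """Average % deviation from baseline over the CR window, split by sign.

    suppression = mean over instants with SDF < baseline of
    (SDF/baseline - 1) * 100; facilitation likewise for SDF > baseline;
    either is 0 when its set is empty.  A ~0 baseline (e.g. complex-spike
    traces) makes the ratio undefined: the trace is flagged invalid.
    """
    g = np.arange(sdf.values.size) if grid is None else np.asarray(grid)
    lo, hi = cr_window
    sel = (g >= lo) & (g < hi)
    vals = sdf.values[sel]
    base = sdf.baseline_mean
    if base <= 1e-9:
        return ModulationResult(0.0, 0.0, 0, 0, valid=False)
    dev = (vals / base - 1.0) * 100.0
    supp = dev[dev < 0.0]
    fac = dev[dev > 0.0]
    return ModulationResult(
        suppression=float(supp.mean()) if supp.size else 0.0,
        facilitation=float(fac.mean()) if fac.size else 0.0,
        n_suppressed=int(supp.size),
        n_facilitated=int(fac.size),
    )


def flag_significant(
    mod: ModulationResult,
    baseline_mod: ModulationResult,
) -> bool:
    """Trace is significant iff its dominant CR-window modulation strictly
    exceeds the corresponding deviation of the baseline window itself."""
    if not mod.valid:
        return False
    if abs(mod.suppression) >= mod.facilitation:
        return abs(mod.suppression) > abs(baseline_mod.suppression)
    return mod.facilitation > baseline_mod.facilitation


def baseline_modulation(
    sdf: SDFTrace,
    baseline_window: tuple[int, int],
) -> ModulationResult:
    """The modulation formula applied to the baseline window itself (the
    significance reference)."""
    return compute_modulation(sdf, baseline_window)


def recruitment(flags: list[bool] | np.ndarray) -> float:
    """% of traces with significant modulation (errors on an empty set)."""
    arr = np.asarray(flags, dtype=bool)
    if arr.size == 0:
        raise ValueError("no traces")
    return float(arr.mean() * 100.0)


def plasticity_curves(
    snapshots: np.ndarray,
    initial: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Per-block plasticity curves of one site.

    ``snapshots``: (n_blocks+1, n_syn), row 0 = initial weights.  Returns
    ``ltd`` (<= 0) and ``ltp`` (>= 0) arrays of length n_blocks: mean %
    weight change of the synapses moving in that direction, multiplied by
    the fraction of synapses doing so.
    """
    snaps = np.asarray(snapshots, dtype=float)
    w0 = snaps[0] if initial is None else np.asarray(initial, dtype=float)
    nz = w0 != 0
    ltd, ltp = [], []
    for w in snaps[1:]:
        pct = np.zeros_like(w0)
        pct[nz] = (w[nz] / w0[nz] - 1.0) * 100.0
        down = pct[pct < 0]
        up = pct[pct > 0]
        n = pct.size
        ltd.append(down.mean() * down.size / n if down.size else 0.0)
        ltp.append(up.mean() * up.size / n if up.size else 0.0)
    return {"ltd": np.array(ltd), "ltp": np.array(ltp)}


def sdf_min_time_distribution(
    sdf_traces: list[SDFTrace],
    cr_window: tuple[int, int],
    bin_ms: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram of SDF-minimum times within the CR window.

    Returns (bin_edges, probabilities)."""
    lo, hi = cr_window
    mins = []
    for tr in sdf_traces:
        win = tr.values[lo:hi]
        mins.append(lo + int(np.argmin(win)))
    edges = np.arange(lo, hi + bin_ms, bin_ms)
    h, _ = np.histogram(mins, bins=edges)
    p = h / h.sum() if h.sum() else h.astype(float)
    return edges, p


def cumulative_square_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Sum of squared bin-probability differences between two histograms."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("histograms must share binning")
    return float(np.sum((p - q) ** 2))
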
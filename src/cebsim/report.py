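"""Experiment-level summaries: learning curves, firing modulation, recruitment.

Bridges the raw :class:`~cebsim.protocol.ExperimentResult` (spikes, weight
snapshots) and the per-trace analysis primitives: conditioned-response
scoring via the motor decoder, and per-trace SDF modulation of the last
block following the measurement conventions of the modelled experiments
(baseline frequency from the first trial's pre-CS window; complex spikes
removed from Purkinje trains before the simple-spike SDF; modulation
averaged over significantly modulated traces).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import (SDF_WIDTH_MS, ModulationResult, compute_modulation,
                       compute_sdf, flag_significant, separate_ss_cs)
from .decoder import control_max_amplitude, learning_curve, score_trials
from .protocol import ExperimentResult, ProtocolConfig
from .scaffold import Network

__all__ = [
    "cr_curves",
    "control_reference_amplitude",
    "ModulationSummary",
    "population_modulation",
    "experiment_last_block_cr",
]


def control_reference_amplitude(result: ExperimentResult,
                                network: Network) -> float:
    """Maximum eye-closure amplitude over all control trials (the
    normalization constant frozen for knock-out runs)."""
    nidx = network.neurons.set_index("id")
    dcn_ids = network.population_ids("DCN_p")
    down = nidx.loc[dcn_ids, "micromodule"].to_numpy() == "downbound"
    mx = 0.0
    for seed_trials in result.trials:
        mx = max(mx, control_max_amplitude(seed_trials, down, result.protocol))
    return mx


def cr_curves(result: ExperimentResult, network: Network,
              control_max: float) -> tuple[np.ndarray, np.ndarray, list]:
    """Learning curve (%CR per block: mean, SD across seeds) and the
    per-seed CR result lists."""
    nidx = network.neurons.set_index("id")
    dcn_ids = network.population_ids("DCN_p")
    down = nidx.loc[dcn_ids, "micromodule"].to_numpy() == "downbound"
    per_seed = [
        score_trials(trials, down, result.protocol, control_max)
        for trials in result.trials
    ]
    mean, sd = learning_curve(per_seed, result.protocol.trials_per_block)
    return mean, sd, per_seed


def experiment_last_block_cr(result: ExperimentResult, network: Network,
                             control_max: float) -> float:
    """%CR of the last block, averaged across seeds."""
    mean, _, _ = cr_curves(result, network, control_max)
    return float(mean[-1])


@dataclass
class ModulationSummary:
    """Per-population modulation statistics of the last block."""

    population: str
    selection: str
    per_trace: list[ModulationResult]
    mean_suppression_significant: float
    mean_facilitation_significant: float
    pct_significant: float
    pct_significant_suppressing: float
    pct_significant_facilitating: float
    mean_change_significant: float   # dominant-direction mean % change


def _cells_of(network: Network, engine_masks: dict, population: str,
              selection: str) -> np.ndarray:
    """Local indices of the selected cells.

    ``selection``: 'downbound'/'upbound' for modular populations,
    'down_pref'/'up_pref' for MLIs (SC+BC handled per population), or 'all'.
    """
    nidx = network.neurons.set_index("id")
    ids = network.population_ids(population)
    if selection in ("downbound", "upbound"):
        mask = nidx.loc[ids, "micromodule"].to_numpy() == selection
    elif selection in ("down_pref", "up_pref"):
        want = "downbound" if selection == "down_pref" else "upbound"
        mask = nidx.loc[ids, "mli_pref"].to_numpy() == want
    else:
        mask = np.ones(ids.size, dtype=bool)
    return np.flatnonzero(mask)


def population_modulation(
    result: ExperimentResult,
    network: Network,
    population: str,
    selection: str = "all",
    signal: str | None = None,
    block: int | None = None,
) -> ModulationSummary:
    """Per-trace SDF modulation over the CR window for one population.

    ``signal``: 'SS' (default for PC: complex spikes removed), 'CS'
    (complex-spike series), or None for the raw train of non-PC
    populations.  ``block``: block index (default: last).  Baseline rates
    for complex-spike separation come from each cell's first-trial baseline
    window, per simulation.
    """
    proto: ProtocolConfig = result.protocol
    T = proto.trial_length
    grid = np.arange(T)
    base_win = (0, proto.baseline_ms)
    cr_win = proto.cr_window
    cells = _cells_of(network, {}, population, selection)
    if signal is None:
        signal = "SS" if population == "PC" else population
    width = SDF_WIDTH_MS["MLI" if population in ("SC", "BC") else
                         ("PC_SS" if (population, signal) == ("PC", "SS")
                          else ("PC_CS" if (population, signal) == ("PC", "CS")
                                else population))]

    per_trace: list[ModulationResult] = []
    flags: list[bool] = []
    for s, seed_trials in enumerate(result.trials):
        blk = (result.protocol.n_blocks - 1) if block is None else block
        trials = result.block_trials(s, blk)
        # per-cell baseline rate from the first trial of this simulation
        first = seed_trials[0]
        ids0, ts0 = first.of(population)
        base_rate = {}
        for c in cells:
            n0 = int(np.sum((ids0 == c) & (ts0 < proto.baseline_ms)))
            base_rate[c] = n0 / (proto.baseline_ms / 1000.0)
        for ti, rec in enumerate(trials):
            ids, ts = rec.of(population)
            for c in cells:
                train = ts[ids == c].astype(float)
                if population == "PC":
                    br = max(base_rate[c], 1.0)
                    ss, cs = separate_ss_cs(train, br)
                    train = ss if signal == "SS" else cs
                sdf = compute_sdf(train, width, grid, base_win, cell_id=c,
                                  trial_index=ti)
                mod = compute_modulation(sdf, cr_win)
                base_mod = compute_modulation(sdf, base_win)
                mod.significant = flag_significant(mod, base_mod)
                per_trace.append(mod)
                flags.append(mod.significant)

    valid = [m for m in per_trace if m.valid]
    sig = [m for m in valid if m.significant]
    sig_sup = [m for m in sig if abs(m.suppression) >= m.facilitation]
    sig_fac = [m for m in sig if m.facilitation > abs(m.suppression)]
    n_valid = max(len(valid), 1)

    def _mean(vals):
        return float(np.mean(vals)) if len(vals) else 0.0

    dominant = ([m.suppression for m in sig_sup]
                + [m.facilitation for m in sig_fac])
    return ModulationSummary(
        population=population,
        selection=selection,
        per_trace=per_trace,
        mean_suppression_significant=_mean([m.suppression for m in sig_sup]),
        mean_facilitation_significant=_mean([m.facilitation for m in sig_fac]),
        pct_significant=100.0 * len(sig) / n_valid,
        pct_significant_suppressing=100.0 * len(sig_sup) / n_valid,
        pct_significant_facilitating=100.0 * len(sig_fac) / n_valid,
        mean_change_significant=_mean(dominant),
    )
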
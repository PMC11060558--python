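"""Columnar on-disk exports of experiment results.

Spike events, motor traces, CR tables and per-block weight snapshots are
written as plain CSV with a JSON manifest recording the configuration hash
and seeds, so runs can be archived and re-analysed without the simulator.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .protocol import ExperimentResult

__all__ = ["save_experiment", "load_spikes", "experiment_manifest"]


def experiment_manifest(result: ExperimentResult) -> dict:
    cfg = {
        "protocol": asdict(result.protocol),
        "lesion": result.lesion.id,
        "network": {
            "scale_factor": result.network_config.scale_factor,
            "downbound_fraction": result.network_config.downbound_fraction,
            "seed": result.network_config.seed,
        },
        "seeds": result.seeds,
    }
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
    return {**cfg, "config_sha256": digest}


def save_experiment(result: ExperimentResult, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / "manifest.json").write_text(
        json.dumps(experiment_manifest(result), indent=2, default=str))

    rows = []
    for s, trials in enumerate(result.trials):
        for ti, rec in enumerate(trials):
            for pop, (ids, ts) in rec.spikes.items():
                if ids.size:
                    rows.append(pd.DataFrame({
                        "seed": s, "trial": ti, "population": pop,
                        "neuron": ids, "t_ms": ts,
                    }))
    spikes = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["seed", "trial", "population", "neuron", "t_ms"])
    spikes.to_csv(d / "spikes.csv", index=False)

    for s, snaps in enumerate(result.weight_snapshots):
        for name, mat in snaps.items():
            df = pd.DataFrame(mat.T)
            df.columns = [f"block_{b}" for b in range(mat.shape[0])]
            df.insert(0, "synapse", np.arange(mat.shape[1]))
            df.to_csv(d / f"weights_seed{s}_{name}.csv", index=False)

    cio = pd.DataFrame({
        f"seed_{s}": flags for s, flags in enumerate(result.cio_delivered)})
    cio.to_csv(d / "cio_delivered.csv", index=False)


def load_spikes(directory: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(directory) / "spikes.csv")
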
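"""Calibration recipe, step 2: network operating point.

Documents and reproduces how the shipped connection-table weights and the
in-network endogenous currents were obtained:

1. Granular-layer contrast: with the spatially local glomerulus sampling,
   the glomerulus->granule weight and the Golgi->granule weight are chosen
   so granule cells are nearly silent on the 1 Hz mossy-fibre background
   (< ~1 Hz) while CS-cylinder granule cells respond during the 10 Hz CS
   (population CS/baseline contrast >= 2, a sparse time-coding regime).
2. Molecular layer: MLI baseline ~20 Hz (endogenous drive from step 1 of
   the recipe plus weak parallel-fibre input); MLI->PC weights small enough
   that the in-network PC baselines stay at the printed class anchors
   (~86 Hz downbound, ~39 Hz upbound) yet large enough that a ~4x MLI
   potentiation suppresses PCs by >= ~10%.
3. Deep nuclei / olive: the DCN_p, DCN_GABA and IO endogenous currents are
   bisected in-network (all other weights fixed) against their baseline
   targets, 67 / ~10 / ~1 Hz, under the running Purkinje inhibition.

This script re-measures the resulting baselines and the granular CS
contrast with the shipped defaults and prints them next to their targets.

Run:  python scripts/calibrate_network.py [--scale 0.1] [--seed 1]
"""

from __future__ import annotations

import argparse

import numpy as np

from cebsim.calibration import baseline_rates
from cebsim.params import BASELINE_TARGETS_HZ
from cebsim.plasticity import PlasticityRuleParams
from cebsim.protocol import (LesionConfig, ProtocolConfig, generate_cs,
                             make_engine, build_default_network)
from cebsim.scaffold import NetworkConfig


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--scale", type=float, default=0.1)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    net = build_default_network(NetworkConfig(scale_factor=args.scale,
                                              seed=args.seed))
    eng = make_engine(net, LesionConfig("control"), PlasticityRuleParams(),
                      np.random.default_rng(0), plasticity_enabled=False)
    rates = baseline_rates(eng, duration_ms=5000,
                           rng=np.random.default_rng(7))
    print("in-network baseline rates (target):")
    for key in ("PC_down", "PC_up", "SC", "BC", "DCN_p", "DCN_GABA", "IO"):
        tgt = BASELINE_TARGETS_HZ.get(key, BASELINE_TARGETS_HZ.get(key.split("_")[0]))
        print(f"  {key:9s} {rates[key]:6.1f} Hz  (target {tgt})")

    # granular-layer CS contrast
    eng2 = make_engine(net, LesionConfig("control"), PlasticityRuleParams(),
                       np.random.default_rng(0), plasticity_enabled=False,
                       recorded=("GrC",))
    proto = ProtocolConfig()
    rng = np.random.default_rng(5)
    eng2.reset_trial_state(rng=rng)
    mf = generate_cs(proto, rng, eng2.cs_mf_mask)
    rec = eng2.run_trial(mf.astype(float))
    ids, ts = rec.of("GrC")
    base = np.sum(ts < proto.cs_onset) / eng2.n["GrC"] / (proto.cs_onset / 1000)
    cs_end = proto.cs_onset + proto.cs_duration_ms
    cs = (np.sum((ts >= proto.cs_onset) & (ts < cs_end)) / eng2.n["GrC"]
          / (proto.cs_duration_ms / 1000))
    print(f"granule cells: baseline {base:.2f} Hz, during CS {cs:.2f} Hz "
          f"(contrast {cs / max(base, 1e-9):.1f}x, target >= 2)")


if __name__ == "__main__":
    main()
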
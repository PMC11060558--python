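"""Calibration recipe, step 3: learning rates of the two plastic sites.

The four rates (LTP_PC, LTD_PC, LTP_MLI, LTD_MLI) are free parameters.
They were balanced, on the reduced protocol, so that the end-of-learning
firing modulation of the downbound populations approaches the reference
values (PC simple spikes ~ -14% suppression, MLIs strongly facilitating,
DCN_p ~ +88% facilitation) while the upbound module keeps the opposite
directions, and then fixed as the shipped defaults together with the
reference protocol length (rates scale linearly with the inverse of the
number of trials; see ``cebsim.plasticity.default_rule_params``).

This script runs a control experiment with the shipped (or overridden)
rates at a reduced size and prints the resulting modulation next to the
targets, which is all the manual recipe needs: raise LTP_MLI/LTD_PC if the
downbound suppression is too shallow, raise LTD_MLI if upbound-preferring
MLIs fail to depress, keep LTP_PC small enough that the double knock-out
does not drift.

Run:  python scripts/calibrate_rates.py [--trials 15] [--blocks 10]
          [--ltp-pc X] [--ltd-pc X] [--ltp-mli X] [--ltd-mli X]
"""

from __future__ import annotations

import argparse

import numpy as np

from cebsim.plasticity import DEFAULT_LEARNING_RATES, PlasticityRuleParams
from cebsim.protocol import (LesionConfig, ProtocolConfig,
                             build_default_network, run_experiment)
from cebsim.report import (control_reference_amplitude, cr_curves,
                           population_modulation)
from cebsim.scaffold import NetworkConfig


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--scale", type=float, default=0.1)
    ap.add_argument("--blocks", type=int, default=10)
    ap.add_argument("--trials", type=int, default=15)
    ap.add_argument("--seeds", type=int, default=1)
    ap.add_argument("--master-seed", type=int, default=1)
    for k in DEFAULT_LEARNING_RATES:
        ap.add_argument(f"--{k.lower().replace('_', '-')}", type=float,
                        default=DEFAULT_LEARNING_RATES[k])
    args = ap.parse_args()

    rates = {k: getattr(args, k.lower()) for k in DEFAULT_LEARNING_RATES}
    print("rates:", rates)
    net = build_default_network(NetworkConfig(scale_factor=args.scale,
                                              seed=args.master_seed))
    proto = ProtocolConfig(n_blocks=args.blocks, trials_per_block=args.trials,
                           n_seeds=args.seeds)
    res = run_experiment(net, proto, PlasticityRuleParams(**rates),
                         LesionConfig("control"),
                         master_seed=args.master_seed, progress=True)
    cmax = control_reference_amplitude(res, net)
    mean, sd, _ = cr_curves(res, net, cmax)
    print("%CR per block:", np.round(mean, 1))
    targets = {("PC", "downbound"): "-14 (suppression)",
               ("DCN_p", "downbound"): "+88 (facilitation)",
               ("SC", "down_pref"): "strong facilitation",
               ("SC", "up_pref"): "suppression-dominated",
               ("PC", "upbound"): "facilitation-leaning"}
    for (pop, sel), tgt in targets.items():
        m = population_modulation(res, net, pop, sel)
        print(f"{pop}/{sel}: suppression {m.mean_suppression_significant:.1f}%, "
              f"facilitation {m.mean_facilitation_significant:.1f}%, "
              f"significant {m.pct_significant:.0f}% "
              f"(sup {m.pct_significant_suppressing:.0f} / "
              f"fac {m.pct_significant_facilitating:.0f})   [target: {tgt}]")


if __name__ == "__main__":
    main()
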
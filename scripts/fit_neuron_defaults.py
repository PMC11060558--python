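"""Calibration recipe, step 1: fit fallback E-GLIF constants to rate anchors.

Reproduces the shipped neuron-parameter defaults in ``cebsim/params.py``:

* Purkinje cells: the two printed drive->rate anchors (176.3 pA -> 39 +/- 1 Hz,
  742.54 pA -> 86 +/- 1 Hz) imply an f-I curve with a positive zero-drive
  intercept, i.e. intrinsic pacemaking; with E_L above V_th, a grid search
  over (C, A2, E_L) under fast spike-triggered adaptation (k2 = 0.1/ms)
  lands both anchors.  The shipped values C=425, A2=700, E_L=-36 give
  39.4 / 85.5 Hz.
* Other autorhythmic populations: the endogenous current I_e is found by
  bisection of the isolated tonic rate against the population's baseline
  target (GoC 8 Hz, SC/BC ~20 Hz, DCN_GABA ~15 Hz).
* IO is left sub-threshold (noise-free tonic rate 0); its ~1 Hz spontaneous
  rate comes from the escape-noise term inside the network.
* DCN_p I_e is calibrated in-network (step 2, scripts/calibrate_network.py)
  because its baseline (~67 Hz) is defined under Purkinje inhibition.

Run:  python scripts/fit_neuron_defaults.py
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from cebsim.neurons import tonic_rate
from cebsim.params import DEFAULT_NEURON_PARAMS, PC_IE_DOWNBOUND, PC_IE_UPBOUND


def fit_pc() -> tuple[float, float, float]:
    base = DEFAULT_NEURON_PARAMS["PC"]
    best = (np.inf, None)
    for E_L in (-38.0, -36.0, -34.0):
        for C in np.arange(350.0, 600.0, 25.0):
            q = base.with_(E_L=E_L, C=C)
            rl = tonic_rate(q, PC_IE_UPBOUND, 5)
            rh = tonic_rate(q, PC_IE_DOWNBOUND, 5)
            err = abs(rl - 39.0) + abs(rh - 86.0)
            if err < best[0]:
                best = (err, (E_L, C, rl, rh))
    E_L, C, rl, rh = best[1]
    print(f"PC: E_L={E_L} C={C} -> {rl:.1f} Hz @ {PC_IE_UPBOUND} pA, "
          f"{rh:.1f} Hz @ {PC_IE_DOWNBOUND} pA (A2={base.A2}, k2={base.k2})")
    return E_L, C, base.A2


def fit_ie(pop: str, target_hz: float, lo: float = 0.5, hi: float = 500.0) -> float:
    p = DEFAULT_NEURON_PARAMS[pop].with_(I_e=0.0)
    ie = brentq(lambda x: tonic_rate(p, x, 10) - target_hz, lo, hi, xtol=0.05)
    print(f"{pop}: I_e = {ie:.2f} pA -> {tonic_rate(p, ie, 10):.2f} Hz (target {target_hz})")
    return ie


if __name__ == "__main__":
    fit_pc()
    fit_ie("GoC", 8.0)
    fit_ie("SC", 20.0)
    fit_ie("BC", 20.0)
    fit_ie("DCN_GABA", 15.0)
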
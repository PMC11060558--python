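"""Default neuron parameters and baseline-rate targets per population.

The parameter sets below are fallback defaults: population-specific E-GLIF
constants fitted so that isolated-neuron tonic rates reproduce the printed
baseline anchors of the modelled circuit (Purkinje cells: 742.54 pA ->
86 +/- 1 Hz for the zebrin-negative/downbound class and 176.3 pA ->
39 +/- 1 Hz for the zebrin-positive/upbound class; molecular-layer
interneurons ~20 Hz; deep-nuclei projection neurons tuned in-network to
~67 Hz under Purkinje inhibition; inferior olive ~1 Hz).  They are produced
by ``scripts/fit_neuron_defaults.py`` (the shipped calibration recipe) and
frozen here.

Capacitance pF, current pA, potential mV, time ms throughout.
"""

from __future__ import annotations

from .neurons import NeuronParams

__all__ = [
    "DEFAULT_NEURON_PARAMS",
    "BASELINE_TARGETS_HZ",
    "PC_IE_DOWNBOUND",
    "PC_IE_UPBOUND",
    "SPIKING_POPULATIONS",
    "RELAY_POPULATIONS",
]

# Endogenous drives for the two Purkinje-cell classes (printed anchors).
PC_IE_DOWNBOUND = 742.54   # Z- PCs, 86 +/- 1 Hz
PC_IE_UPBOUND = 176.3      # Z+ PCs, 39 +/- 1 Hz

SPIKING_POPULATIONS = ("GrC", "GoC", "PC", "SC", "BC", "DCN_p", "DCN_GABA", "IO")
RELAY_POPULATIONS = ("mf", "glom")

# Target in-network baseline firing rates (Hz) used by weight calibration.
BASELINE_TARGETS_HZ = {
    "GrC": 0.5,
    "GoC": 8.0,
    "PC_down": 86.0,
    "PC_up": 39.0,
    "SC": 20.0,
    "BC": 20.0,
    "DCN_p": 67.0,
    "DCN_GABA": 10.0,
    "IO": 0.1,
}

# Fallback E-GLIF parameter sets (see module docstring).  PC I_e is the
# downbound value; the engine overrides I_e per cell class.
DEFAULT_NEURON_PARAMS: dict[str, NeuronParams] = {
    # Granule cells: small, silent at rest, fire on coincident glomerular input.
    "GrC": NeuronParams(
        C=3.1, tau_m=24.15, E_L=-62.0, V_th=-41.0, V_reset=-70.0,
        I_e=0.0, k_adap=0.022, k2=0.041, k1=0.311, A1=0.01, A2=0.5,
        t_ref=1.5,
    ),
    # Golgi cells: slow autorhythm (~8 Hz).
    "GoC": NeuronParams(
        C=145.0, tau_m=44.0, E_L=-62.0, V_th=-55.0, V_reset=-75.0,
        I_e=30.84, k_adap=0.05, k2=0.05, k1=0.031, A1=10.0, A2=20.0,
        t_ref=2.0,
    ),
    # Purkinje cells: intrinsic pacemaker (depolarized E_L, the two printed
    # drive->rate anchors imply a positive zero-drive intercept of the f-I
    # curve); C and A2 fitted so 176.3 pA -> ~39 Hz and 742.54 pA -> ~86 Hz.
    "PC": NeuronParams(
        C=435.0, tau_m=28.5, E_L=-36.0, V_th=-43.0, V_reset=-55.0,
        I_e=PC_IE_DOWNBOUND, k_adap=0.3, k2=0.05, k1=0.195, A1=200.0,
        A2=350.0, t_ref=1.5, escape_sigma=0.5, escape_rate=0.2,
    ),
    # Stellate cells (~20 Hz autorhythm).
    "SC": NeuronParams(
        C=14.6, tau_m=9.125, E_L=-68.0, V_th=-53.0, V_reset=-78.0,
        I_e=29.13, k_adap=0.015, k2=0.041, k1=0.311, A1=3.0, A2=3.0,
        t_ref=1.59,
    ),
    # Basket cells (~20 Hz autorhythm).
    "BC": NeuronParams(
        C=14.6, tau_m=9.125, E_L=-68.0, V_th=-53.0, V_reset=-78.0,
        I_e=29.13, k_adap=0.015, k2=0.041, k1=0.311, A1=3.0, A2=3.0,
        t_ref=1.59,
    ),
    # Deep-nuclei projection neurons: high intrinsic drive, strong rebound
    # machinery; the in-network baseline under PC inhibition is ~67 Hz.
    "DCN_p": NeuronParams(
        C=142.0, tau_m=33.0, E_L=-45.0, V_th=-36.0, V_reset=-55.0,
        I_e=1075.0, k_adap=0.8, k2=0.02, k1=0.156, A1=150.0, A2=100.0,
        t_ref=1.5, escape_sigma=0.5, escape_rate=0.2,
    ),
    # GABAergic nucleo-olivary neurons: slower, lower rate.
    "DCN_GABA": NeuronParams(
        C=56.0, tau_m=56.0, E_L=-50.0, V_th=-39.0, V_reset=-55.0,
        I_e=460.0, k_adap=0.079, k2=0.044, k1=0.141, A1=3.0, A2=60.0,
        t_ref=3.0, escape_sigma=0.5, escape_rate=0.2,
    ),
    # Inferior olive: sub-threshold at rest; spontaneous ~1 Hz firing comes
    # from the stochastic escape term (noise-free tonic rate is 0), while
    # afferent bursts transfer reliably.
    "IO": NeuronParams(
        C=189.0, tau_m=11.0, E_L=-45.0, V_th=-35.0, V_reset=-45.0,
        I_e=280.0, k_adap=1.928, k2=0.091, k1=0.191, A1=200.0, A2=1500.0,
        t_ref=1.0, escape_sigma=1.0, escape_rate=0.002,
    ),
}
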
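"""Extended generalized leaky integrate-and-fire (E-GLIF) point neurons.

The E-GLIF model augments the leaky integrator with two spike-coupled
currents: an adaptation current ``I_adap`` (negative feedback, coupled to the
membrane potential through ``k_adap`` and incremented by ``A2`` at each
spike) and a fast depolarization current ``I_dep`` (set to ``A1`` at each
spike, decaying with rate ``k1``).  This combination supports the salient
electroresponsive features of cerebellar neurons with a three-variable
linear system: tonic autorhythmic firing driven by the endogenous current
``I_e``, an approximately linear frequency-current relationship, burst-pause
responses to strong transient excitation, and rebound bursting after release
from hyperpolarization.

Units used throughout: capacitance pF, currents pA, potentials mV, time ms.
Sub-threshold dynamics between spikes:

    dV/dt      = -(V - E_L)/tau_m + (I_e + I_syn + I_dep - I_adap)/C
    dI_adap/dt = k_adap * (V - E_L) - k2 * I_adap
    dI_dep/dt  = -k1 * I_dep

On a spike: V -> V_reset, I_adap += A2, I_dep = A1, and the neuron is
refractory (V clamped at V_reset) for ``t_ref`` ms.  Spike emission uses a
hard threshold when escape noise is disabled, otherwise a stochastic escape
rate that grows exponentially as V approaches threshold.  The update order
within a 1-ms step is: integrate state, test threshold/escape, apply reset
and spike-triggered current updates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "NeuronParams",
    "NeuronState",
    "EglifPopulation",
    "step_neuron",
    "tonic_rate",
    "relay",
]


@dataclass(frozen=True)
class NeuronParams:
    """Parameter set for one E-GLIF neuron (or one homogeneous population)."""

    C: float          # membrane capacitance, pF
    tau_m: float      # membrane time constant, ms
    E_L: float        # resting potential, mV
    V_th: float       # spike threshold, mV
    V_reset: float    # reset potential, mV
    I_e: float        # endogenous (autorhythm) current, pA
    k_adap: float     # V -> I_adap coupling, pA / (mV ms)
    k2: float         # adaptation decay rate, 1/ms
    k1: float         # depolarization-current decay rate, 1/ms
    A1: float         # spike-triggered depolarization current, pA
    A2: float         # spike-triggered adaptation increment, pA
    t_ref: float      # absolute refractory period, ms
    escape_sigma: float = 0.0   # mV; 0 disables stochastic escape
    escape_rate: float = 0.05   # 1/ms escape rate at V = V_th

    def __post_init__(self) -> None:
        if self.tau_m <= 0 or self.C <= 0:
            raise ValueError("tau_m and C must be positive")
        if self.t_ref < 0:
            raise ValueError("t_ref must be >= 0")
        if self.I_e < 0:
            raise ValueError("I_e must be >= 0")

    def with_(self, **kw) -> "NeuronParams":
        return replace(self, **kw)


@dataclass
class NeuronState:
    """Dynamic state of a single E-GLIF neuron."""

    V: float
    I_adap: float = 0.0
    I_dep: float = 0.0
    refractory: float = 0.0   # remaining refractory time, ms


def step_neuron(
    state: NeuronState,
    params: NeuronParams,
    synaptic_current: float,
    dt: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[NeuronState, bool]:
    """Advance one neuron by ``dt`` (ms); return (new state, spiked flag).

    ``synaptic_current`` is the total synaptic current in pA.  NaN or Inf
    input raises rather than silently corrupting the state.
    """
    if not np.isfinite(synaptic_current):
        raise ValueError(f"non-finite synaptic current: {synaptic_current}")
    pop = EglifPopulation(1, params, rng=rng)
    pop.V[0] = state.V
    pop.I_adap[0] = state.I_adap
    pop.I_dep[0] = state.I_dep
    pop.refractory[0] = state.refractory
    spiked = pop.step(np.array([synaptic_current]), dt=dt)
    new = NeuronState(
        V=float(pop.V[0]),
        I_adap=float(pop.I_adap[0]),
        I_dep=float(pop.I_dep[0]),
        refractory=float(pop.refractory[0]),
    )
    return new, bool(spiked[0])


class EglifPopulation:
    """Vectorized E-GLIF update for ``n`` neurons sharing a parameter set.

    Per-neuron heterogeneity of the endogenous current is supported through
    ``I_e_override`` (used e.g. for the two Purkinje-cell zebrin classes).
    """

    def __init__(
        self,
        n: int,
        params: NeuronParams,
        I_e_override: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
    ):
        self.n = int(n)
        self.p = params
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self.I_e = np.full(self.n, params.I_e, dtype=np.float64)
        if I_e_override is not None:
            self.I_e[:] = I_e_override
        self.V = np.full(self.n, params.E_L, dtype=np.float64)
        self.I_adap = np.zeros(self.n)
        self.I_dep = np.zeros(self.n)
        self.refractory = np.zeros(self.n)

    def randomize_potentials(self, rng: np.random.Generator | None = None) -> None:
        """Draw initial potentials uniformly in [V_reset, V_th) to
        desynchronize autorhythmic populations."""
        r = rng if rng is not None else self.rng
        self.V[:] = r.uniform(self.p.V_reset, self.p.V_th, size=self.n)

    def reset(self) -> None:
        self.V[:] = self.p.E_L
        self.I_adap[:] = 0.0
        self.I_dep[:] = 0.0
        self.refractory[:] = 0.0

    def step(self, I_syn: np.ndarray, dt: float = 1.0) -> np.ndarray:
        """Advance all neurons by ``dt``; return boolean spike vector."""
        p = self.p
        if not np.all(np.isfinite(I_syn)):
            raise FloatingPointError("non-finite synaptic current")
        active = self.refractory <= 0.0
        dV = dt * (
            -(self.V - p.E_L) / p.tau_m
            + (self.I_e + I_syn + self.I_dep - self.I_adap) / p.C
        )
        dIa = dt * (p.k_adap * (self.V - p.E_L) - p.k2 * self.I_adap)
        # keep the explicit update inside the physiological range (matching
        # the network engine's reversal-potential clamp)
        np.clip(dV, -30.0 * dt, 30.0 * dt, out=dV)
        self.V = np.where(active, self.V + dV, p.V_reset)
        np.clip(self.V, -90.0, 10.0, out=self.V)
        self.I_adap += dIa
        self.I_dep -= dt * p.k1 * self.I_dep
        self.refractory = np.maximum(self.refractory - dt, 0.0)

        if p.escape_sigma > 0.0:
            # stochastic escape: hazard rises exponentially near threshold
            x = np.clip((self.V - p.V_th) / p.escape_sigma, -30.0, 30.0)
            p_spike = 1.0 - np.exp(-dt * p.escape_rate * np.exp(x))
            spiked = active & (self.rng.random(self.n) < p_spike)
        else:
            spiked = active & (self.V >= p.V_th)

        if np.any(spiked):
            self.V[spiked] = p.V_reset
            self.I_adap[spiked] += p.A2
            self.I_dep[spiked] = p.A1
            self.refractory[spiked] = p.t_ref
        return spiked


def tonic_rate(
    params: NeuronParams,
    drive: float,
    duration: float = 10.0,
    dt: float = 0.1,
) -> float:
    """Mean firing rate (Hz) of an isolated neuron under constant drive (pA).

    The endogenous current is replaced by ``drive``; escape noise is
    disabled so the result is deterministic.  ``duration`` is in seconds and
    should be >= 5 s for a sub-Hz estimate at tens of Hz.  The default
    integration step is finer than the 1-ms network grid because this is a
    single-neuron measurement: on a 1-ms grid inter-spike intervals are
    integer-quantized, which biases the rate estimate by several Hz at
    ~90 Hz.
    """
    p = params.with_(I_e=float(drive), escape_sigma=0.0)
    pop = EglifPopulation(1, p)
    steps = int(round(duration * 1000.0 / dt))
    count = 0
    zero = np.zeros(1)
    for _ in range(steps):
        count += int(pop.step(zero, dt=dt)[0])
    return count / duration


def relay(spikes_in: np.ndarray) -> np.ndarray:
    """Relay unit: transmit the incoming spike train unchanged.

    Mossy fibres and glomeruli are relays; per-target conduction delays are
    applied downstream by the synapse machinery, not here.
    """
    t = np.asarray(spikes_in, dtype=float)
    if t.ndim != 1:
        raise ValueError("spike train must be one-dimensional")
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise ValueError("spike times must be sorted")
    return t.copy()
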
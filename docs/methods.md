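# Methods

`cebsim` simulates classical eyeblink conditioning (CEBC) in a mesoscale
spiking model of the olivocerebellar circuit: cerebellar cortex (granule,
Golgi, Purkinje, stellate and basket cells with mossy-fibre/glomerulus relay
inputs), deep cerebellar nuclei (glutamatergic projection neurons DCN_p and
GABAergic nucleo-olivary neurons DCN_GABA) and inferior olive (IO), split
into a *downbound* and an *upbound* micromodule.  This note records the
model, its assumptions, the calibration procedure, and what the synthetic
protocol does and does not establish.

## Network scaffold

Construction is statistical.  Every neuron receives a parasagittal
coordinate `x ∈ [0, 1)`; Purkinje, DCN and IO cells with `x < 0.7` form the
downbound module (exactly `round(0.7·n)` cells per population), the rest
the upbound module.  Granular-layer elements and molecular-layer
interneurons (MLIs) are shared.  Connectivity is sampled per connection
type to honour a target mean in-degree (convergence); under down-scaling
the convergence is held constant until the presynaptic pool caps it, which
preserves per-neuron input statistics.  Spatially confined axons and
dendrites (glomerular dendrites, ascending axons, Golgi and MLI axons) are
realized by sampling presynaptic partners inside a window of the
parasagittal coordinate; parallel-fibre types are global.  The spatial
window is what realizes the CS "cylinder": the central 45/117 mossy fibres
map to central glomeruli, and granule cells near the mid-coordinate receive
predominantly CS-driven glomeruli.  Types interconnecting PC, DCN and IO
are confined within a micromodule.  IO spillover onto MLIs follows a steep
linear parasagittal ramp (downbound climbing fibres for `x ≲ 0.6`, upbound
for `x ≳ 0.75`), so MLIs that mostly inhibit downbound Purkinje cells are
also the ones supervised by the downbound olive.  Each MLI is labelled
downbound-/upbound-preferring by the majority module of its PC targets
(ties: climbing-fibre in-degree, then id parity).

Population counts at scale 1 reproduce the reference cortical volume
(29,230 cortical neurons; 117 mossy fibres + 2,336 glomeruli).  DCN and IO
counts (80 DCN_p, 40 DCN_GABA, 40 IO) and all degrees, weights and delays
are **fallback defaults** — the source supplementary tables are not
redistributed here — chosen to preserve plausible convergence ratios and
calibrated as described below.  Golgi-cell gap junctions are approximated
as fast bidirectional depolarizing spike coupling between neighbouring GoCs
and kept outside the 24 chemical connection types.

## Neurons

All spiking cells are E-GLIF point neurons: a leaky integrator with an
adaptation current (coupled to voltage by `k_adap`, decaying at `k2`,
incremented by `A2` per spike) and a fast spike-triggered depolarization
current (`A1`, decay `k1`).  Mossy fibres and glomeruli are relay units.
Units: pF, pA, mV, ms.  The printed Purkinje drive values (176.3 / 742.54)
are interpreted as pA — the only unit dimensionally consistent with
hundreds-of-pF membrane capacitances.

The two printed Purkinje anchors (176.3 pA → 39 ± 1 Hz, 742.54 pA →
86 ± 1 Hz) imply an f–I curve with a positive zero-drive intercept, i.e.
intrinsic pacemaking; the fallback PC parameters therefore place the
resting potential above threshold (E_L = −36 mV, V_th = −43 mV) and fit
(C, A2) to the two anchors.  Strong spike-triggered adaptation yields the
burst-then-pause response to climbing-fibre input.  A consequence of that
same adaptation is that the PC's post-hyperpolarization rebound expresses
as shortened inter-spike intervals once firing resumes rather than as an
increased spike count over a long window; DCN_p cells, with slower
adaptation (τ = 50 ms), show a genuine rebound burst.  Single-neuron rate
anchors are measured at a 0.1-ms step because on the 1-ms network grid
inter-spike intervals are integer-quantized (86 Hz is unreachable
deterministically between 83.3 and 90.9 Hz).

Numerical safeguards for the explicit 1-ms update: the per-step voltage
change is bounded (±30 mV) and the potential is clamped to the
reversal-potential range [−88, +10] mV (on small cells such as granule
cells, conductances above ~1.5 nS would otherwise make the explicit update
oscillate).  Escape noise (a stochastic threshold hazard) is enabled for
PC, DCN_p, DCN_GABA and IO; it models "single-neuron noise", desynchronizes
cells that share afferents at reduced scale, and gives the IO a low
spontaneous rate (~0.1 Hz; the IO is deterministically sub-threshold at
rest).  The spontaneous rate is kept deliberately low: every stray IO spike
is a teaching event, and with the strong depression rate the upbound
module — which receives no US-related climbing-fibre signal — would
otherwise accumulate enough spurious depression to reverse its net
potentiation.

## Synapses and plasticity

Synapses are alpha-shaped conductance transients (peak = weight at
t = τ_syn) with per-type delays, implemented by an exact two-state
recurrence on the grid; excitatory reversal 0 mV, inhibitory −88 mV.

Two supervised plasticity sites, both gated by climbing-fibre (cf)
activity, evaluated at spike *arrival* times (presynaptic time + delay),
with "coincident" meaning the same 1-ms step:

* **pf–PC**: a cf spike depresses each parallel-fibre synapse of its target
  PC by `LTD_PC ×` (number of pf arrivals in the preceding 200 ms — the
  fallback constant-window eligibility kernel, used because the original
  closed form is not redistributed); a pf arrival without coincident cf
  potentiates by `LTP_PC`.
* **pf–MLI**: sign-reversed — a cf spike potentiates by `LTP_MLI × Σ K(Δt)`
  over prior pf arrivals, with the alpha kernel `K(t) = (t/τ)e^(1−t/τ)`,
  τ = 50 ms, truncated at 10τ (the online eligibility trace realizes this
  convolution exactly, to float precision, which the tests verify against a
  brute-force double loop); a pf arrival without coincident cf depresses by
  `LTD_MLI`.

Weights are clipped to [0, 4 × initial]; the upper bound does not bind in
control runs.  Lesions: `ltd_ko` sets LTD_PC = 0, `mli_ko` zeroes the
SC→PC/BC→PC conductances, `double_ko` both.

The four learning rates are free parameters.  The shipped defaults were
produced by the calibration recipe (`scripts/calibrate_rates.py`): balance
the rates on the reduced protocol until the end-of-learning modulation of
the downbound populations approaches the reference values (PC simple
spikes ≈ −14%, DCN_p strongly facilitating, MLIs strongly facilitating)
with opposite directions upbound, then fix them together with the
reference protocol length (250 trials).  Rates scale linearly with the
inverse of the trial count (`default_rule_params(total_trials)`), the same
linear-rescaling logic used to transfer rates tuned on short sequences to
long ones.

## Protocol

A trial is 1,260 ms: 500 ms baseline, 260 ms CS (10 Hz Poisson on the
central mossy-fibre subset, over a 1 Hz background on all mfs), US = 500 Hz
× 10 ms to every downbound IO cell, co-terminating with the CS
(ISI = 250 ms; 200/300 ms variants adjust the CS duration), 500 ms post.
The conditioned IO response (CIO) is a 400 Hz × 10 ms burst to a fixed
random half of the downbound IO cells at 88 ms after CS onset, occurring
with probability ramping linearly to 0.43 at the end of learning.  US and
CIO inputs reach the IO through a strong fast synapse so each input burst
reliably transfers.  Trials are contiguous stretches of simulated time
(ring buffers, conductances and eligibility traces persist); each seed
starts with randomized potentials and a 500-ms settle period.  All
randomness derives from a master seed through separate streams for
construction and per-seed stimuli/noise, so lesions never perturb the
wiring and runs replay bit-identically.

## Motor decoding and CR detection

Per micromodule, the DCN_p per-capita instantaneous rate (so the 70/30
size split does not bias amplitude) is smoothed by a 20-ms moving average
and a Gaussian window (25 ms width, interpreted as the standard deviation
everywhere in this package); the net signal is downbound − upbound, with
zero padding at trial edges (constant-mode filtering) so edge bins cannot
masquerade as responses.  Per trial the pre-CS baseline mean is subtracted;
amplitudes are normalized by the maximum over all control trials, frozen
and reused for knock-out runs.  A CR is scored when the normalized signal
reaches `max(0.2, mean + 2.5·SD of baseline)` in the last 200 ms of the ISI
(the first 50 ms are excluded as non-associative); the floor is applied to
the threshold, not by excluding trials.  Onset = first crossing; peak =
argmax from onset to the end of the trial.

## Analysis

Spike density functions are Gaussian-kernel rate estimates (41 ms for
PC-SS/MLI, 10 ms for DCN_p, 5 ms for PC-CS/IO), boundary-corrected by the
kernel mass falling inside the trial (otherwise the pre-CS baseline is
underestimated by ~15% and every modulation is biased).  Purkinje complex
spikes are maximal runs of ≥ 2 spikes at instantaneous rate above twice the
cell's baseline (first-trial pre-CS rate), replaced by a single spike in
the simple-spike series.  Modulation of a trace is the mean percent
deviation from its baseline over the CR window, split into suppression
(instants strictly below baseline) and facilitation (strictly above;
equal-to-baseline instants belong to neither).  A trace is significant when
its dominant CR-window deviation strictly exceeds the deviation the same
formula yields on the whole baseline window (a deliberate choice; the
baseline reference window length is not otherwise specified).  Plasticity
curves report, per block, mean percent weight change of synapses moving in
each direction times the fraction moving that way.

## Problem sizes and what the tests show

Full-scale runs (29k neurons × 1,000 trials) are not desk-feasible; the
shipped experiments run at scale 0.1 (2,924 cortical neurons, ~60k
synapses) with 10 blocks of 15–25 trials and 2–3 seeds, with the learning
rates rescaled accordingly.  End-of-learning %CR in tests is averaged over
the last three blocks — the same end-of-learning window used for CR-gain
summaries — because a single reduced-size block is a noisy estimator.  At
this scale the upbound module contains only 2–3 DCN_p cells, so
upbound-module statistics are coarse; the downbound module and the
aggregate behaviour (learning curves, lesion ordering, firing modulation)
are the validated quantities.  Synthetic stimuli are stationary Poisson
processes; real mossy-fibre input carries richer temporal structure, so
passing tests establish the circuit and plasticity mechanisms, not
quantitative predictions for any particular sensory pathway.

## Known limitations

* DCN/IO counts, degrees, weights, delays and all E-GLIF constants are
  calibrated fallbacks, not transcriptions of the original tables; the
  pf–PC eligibility kernel is the constant-window fallback.
* No short-term plasticity, nuclear plasticity, intrinsic-excitability
  plasticity, or multicompartmental dendrites.
* Golgi gap junctions are a spike-coupling approximation.
* The Purkinje rebound at the single-neuron level expresses in the
  resumption inter-spike intervals, not in long-window spike counts.
* The anticipated CR peak of the MLI-output knock-out is not reproduced at
  reduced scale: conditioned-IO rebound transients (~140-160 ms after CS
  onset) dominate the control peak-latency distribution because the small
  granular layer time-codes the CS too weakly for the learned suppression
  to ramp toward the US.  The delayed onset and peak of the LTD and double
  knock-outs are reproduced.
* The 1-ms explicit integrator requires the voltage clamps above;
  sub-millisecond synaptic dynamics are not resolved.
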
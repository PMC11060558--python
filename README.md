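# cebsim

A scale-configurable spiking simulator of classical eyeblink conditioning
(CEBC) in the olivocerebellar circuit.

## The scientific problem

In eyeblink conditioning, a neutral conditioned stimulus (CS — a tone or
LED, conveyed by mossy fibres) is repeatedly followed, at a fixed
inter-stimulus interval (ISI), by an unconditioned stimulus (US — an air
puff, encoded by the inferior olive and conveyed by climbing fibres).  The
cerebellum learns a well-timed anticipatory eyelid closure, the conditioned
response (CR).  Recent evidence indicates that this learning is not carried
by parallel-fibre → Purkinje-cell depression alone: it is distributed over
at least two microzones with opposite firing tendencies — a *downbound*
module (zebrin-negative Purkinje cells, high baseline rate, recipient of
the US teaching signal, prone to simple-spike suppression) and an *upbound*
module (zebrin-positive, low baseline, prone to facilitation) — and over
two climbing-fibre-supervised plasticity sites with opposite signs:

* **pf–PC**: cf-gated long-term depression,
  `ΔW = −LTD_PC · Σ_pf-spikes K_PC(t_cf − t_pf)` at each cf spike, and
  `ΔW = +LTP_PC` for each pf spike without coincident cf activity;
* **pf–MLI** (molecular-layer interneurons, i.e. stellate/basket cells):
  sign-reversed — `ΔW = +LTP_MLI · Σ K(t_cf − t_pf)` with the alpha kernel
  `K(t) = (t/τ)·e^(1−t/τ)`, τ = 50 ms, and `ΔW = −LTD_MLI` per unsupervised
  pf spike.

`cebsim` builds this two-micromodule network from E-GLIF point neurons
(29,230 cortical neurons at full scale, scalable down by a single factor),
runs the full CS/US trial protocol — including the conditioned IO response
(CIO), a learned climbing-fibre burst at 88 ms after CS onset whose
probability ramps to 0.43 — decodes the deep-nuclei output into an analog
eyelid signal with thresholded CR detection
(`threshold = max(0.2, mean + 2.5·SD of baseline)`), and reproduces the
knock-out experiments: pf-PC LTD KO, MLI-output KO, and the double KO that
largely abolishes learning.  The package is written for computational
neuroscientists studying distributed cerebellar plasticity and for anyone
who needs a compact, fully scriptable CEBC benchmark circuit.

## Worked example

Build a 10%-scale network and inspect it:

```
$ cebsim build --scale 0.1 --seed 1 --out netdir
built network at scale 0.1: 2924 cortical neurons, 46035 synapses, 24 connection types
{
  "GrC": 2862,
  "glom": 234,
  "SC": 30,
  "BC": 15,
  "mf": 12,
  "PC": 10,
  "DCN_p": 8,
  "GoC": 7,
  "IO": 4,
  "DCN_GABA": 4
}
```

2,924 cortical neurons is 10% of the full-scale 29,230; the 24 connection
types are the 15 cortical ones plus the 9 added by the deep-nuclei/olive
extension.  Run a conditioning experiment and analyze it from Python:

```python
import numpy as np
from cebsim import NetworkConfig, LesionConfig, build_default_network
from cebsim.protocol import ProtocolConfig, run_experiment
from cebsim.plasticity import default_rule_params
from cebsim.report import (control_reference_amplitude, cr_curves,
                           population_modulation)

net = build_default_network(NetworkConfig(scale_factor=0.1, seed=1))
proto = ProtocolConfig(n_blocks=10, trials_per_block=15, n_seeds=3)
res = run_experiment(net, proto, default_rule_params(proto.total_trials),
                     LesionConfig("control"), master_seed=1)
cmax = control_reference_amplitude(res, net)
mean, sd, _ = cr_curves(res, net, cmax)
print(np.round(mean, 1))
m = population_modulation(res, net, "PC", "downbound", signal="SS")
print(round(m.mean_suppression_significant, 1))
```

This prints a %CR learning curve rising over the ten 15-trial blocks,
e.g.

```
[26.7 46.7 75.6 75.6 75.6 91.1 82.2 80.  82.2 82.2]
```

— a bounded-exponential-shaped acquisition reaching ~80% CR — and the mean
simple-spike suppression of significantly modulated downbound Purkinje
traces in the last block (about −25%, i.e. inside the −14 ± 12 reference
band).  Knock-out runs (`LesionConfig("ltd_ko" | "mli_ko" | "double_ko")`)
reuse the control normalization constant `cmax`; individual knock-outs end
near the control level while the double knock-out stays much lower, carried
mostly by the conditioned IO response.

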
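# enkit — a time-encoding layer for EEG CNN classifiers

Convolutional networks classify EEG epochs well from local and global
spatial-spectral structure, but they have no built-in notion of *when*
things happen inside an epoch — and for event-related potentials such
as the P300 (a positive parietal deflection ~300 ms after a rare
target) the timing *is* the feature.  `enkit` implements a trainable
**encoding kernel (EnK)** layer that injects time information into any
CNN by additively decomposing the signal after the first convolution,
in the spirit of classical time-series decomposition:

```
Z_t = w_t · X_t + b_t                      per-time-step affine
P_t = sin(Z_t)                             periodic component
S_t = Z_t · P_t                            seasonal component
A   = X ⋆ K                                artifact component
                                           (sliding kernel, zero same-padding)

enk(X)_t = Z_t                 if t = 0
enk(X)_t = P_t + S_t + A_t     if t ≥ 1
```

The layer is shape-preserving, adds only `2k' + l·m` parameters
(`k'` = time samples at the insertion point, `K ∈ R^{l×m}`), trains by
backpropagation, and can be spliced into any architecture directly
after its first convolution.

The package is a self-contained laboratory for the layer, aimed at
BCI/neural-engineering researchers who want to study time-encoding
layers without touching real recordings:

- `enkit.enk_core` — the decomposition and its analytic gradients;
- `enkit.models` — EEGNet-8,2, ShallowConvNet, DeepConvNet and a
  recurrent CNN, each with a declarative EnK insertion point, all on a
  built-in numpy network engine (no deep-learning framework needed);
- `enkit.simulate` — a seeded synthetic EEG generator (1/f background,
  class-conditional ERPs, oscillatory bursts, blink and line-noise
  artifacts) with presets for P300-like, cognitive-conflict-like,
  motor-imagery-like and movement-related tasks;
- `enkit.train_eval` — stratified 60/20/20 splits, Adam with early
  stopping, MSE/F1 reports, and exactly paired with/without-EnK runs;
- `enkit.interpret` — Grad-CAM over the first convolution (or the EnK)
  with raw-signal overlays and difference maps;
- an `enkit` command-line interface driving the whole pipeline from one
  YAML config.

## Worked example

Decompose a toy series (one channel, four samples) with the default
near-pass-through parameters (`w = 1`, `b = 0`, `K` a 1×3 averaging
kernel):

```python
import numpy as np
from enkit.enk_core import init_params, enk_forward

x = np.array([[0.5, -1.0, 2.0, 0.25]])
d = enk_forward(x, init_params(n=1, k=4, l=1, m=3))
for name in ("Z", "P", "S", "A", "Y"):
    print(name, np.round(getattr(d, name)[0], 4))
```

```
Z [ 0.5  -1.    2.    0.25]
P [ 0.4794 -0.8415  0.9093  0.2474]
S [0.2397 0.8415 1.8186 0.0619]
A [-0.1667  0.5    0.4167  0.75  ]
Y [0.5    0.5    3.1446 1.0593]
```

`Z` is the affine pre-activation (identity here), `P` its sine,
`S = Z·P`, `A` the zero-padded moving average, and the output takes
`Z` at `t = 0` and `P + S + A` afterwards (e.g.
`0.9093 + 1.8186 + 0.4167 = 3.1446`).

To run the full paired experiment — EEGNet trained with and without the
EnK on the P300-like task (400 epochs, 8 channels, 128 samples, 1 s at
128 Hz) — from the shell:

```bash
cat > demo.yaml <<'YAML'
seed: 7
out: runs/demo
dataset: {preset: p300_like}
model: {architecture: eegnet}
YAML
enkit run --config demo.yaml
```

This simulates the data, trains both arms from identical seeds (same
split, same initial weights, same batch order), evaluates on the held-
out test set and renders Grad-CAM overlays.  It prints:

```json
{
  "delta_mse": -0.006121826786381126,
  "delta_f1": 0.0,
  "mse": {"off": 0.01246369996716823, "on": 0.006341873180787103},
  "f1":  {"off": 0.9876543209876543,  "on": 0.9876543209876543}
}
```

i.e. on this run both arms classify the 80-epoch test partition at
F1 0.988 while the EnK arm halves the MSE (one-hot vs softmax
probabilities) from 0.0125 to 0.0063 — better-calibrated probabilities
at equal accuracy.  The run directory contains both reports, training
histories, checkpoints, the Grad-CAM overlays and a manifest with
every seed and hash needed to re-execute the run.

## Documentation

`docs/methods.md` describes the model and its assumptions, every
default parameter with units and rationale, what the synthetic
generator does and does not emulate, the numerical conventions
(padding, boundary rules, normalisations), and known limitations.
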
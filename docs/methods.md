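# Methods

## The model: additive time-encoding of epoch tensors

`enkit` implements a trainable *encoding kernel* (EnK) layer that
decomposes a windowed multichannel signal into three additive
components, following the classical additive decomposition of a time
series into trend-cycle, seasonal and remainder parts.  For an input
tensor `X` with time index `t = 0 … k−1` (time is always the last
axis), per-time-step weights `w_t` and biases `b_t`, and a small
artifact kernel `K ∈ R^{l×m}`:

- **pre-activation** `Z_t = w_t · X_t + b_t` — an affine map applied
  per time step and broadcast over batch, feature-map and channel axes;
- **periodic component** `P_t = sin(Z_t)` — a bounded sinusoidal
  carrier for the oscillatory structure of EEG (delta 1–3.5 Hz through
  gamma 35+ Hz); `P ∈ [−1, 1]` by construction;
- **seasonal component** `S_t = Z_t · P_t` — the affine term modulated
  by the periodic one, restoring signal-dependent variance that a pure
  sinusoid cannot carry; `|S| ≤ |Z|` always holds when the two
  components share the affine (the default);
- **artifact component** `A` — a sliding cross-correlation of `X` with
  `K` over the (channel, time) plane, zero "same" padding, stride 1,
  no kernel flip.  A small learned smoothing kernel stands in for the
  band-pass denoising that targets the very-low (<1 Hz) and high
  (>45 Hz) frequency artifact bands.

The combined output is

```
Y_t = Z_t            if t = 0
Y_t = P_t + S_t + A_t   if t ≥ 1
```

The first sample receives the plain affine only; this resolves the
overlap between the two defining branches in favour of the `t = 0`
branch, a deliberate design choice (the alternative — including `A_0` —
is not derivable from the defining equations; the chosen rule makes
the zero-parameter limit exact and testable: `w = b = 0` gives
`Y_0 = 0` and `Y_t = A_t`).

The transform is shape-preserving and differentiable; its
vector-Jacobian product is derived analytically
(`dY/dZ = cos Z · (1 + Z) + sin Z` for `t ≥ 1` with a shared affine)
and verified against central finite differences at 1e−4 relative
tolerance.

### Design choices in the layer

- **Shared affine (default).** The periodic and seasonal definitions
  use the same `w_t, b_t` symbols; we read this literally.
  `shared_affine=False` learns a second, independent affine for the
  seasonal term (the `|S| ≤ |Z|` bound then no longer holds).
- **Per-time-step scalars.** `w_t, b_t` are scalars broadcast across
  channels and feature maps — one parameter set per layer, so an EnK
  adds exactly `2k' + l·m` parameters, where `k'` is the time length at
  its insertion point.
- **Axis convention.** "Time" is the last tensor axis everywhere; the
  layer encodes position along time, not across electrodes.
- **Artifact kernel default `l=1, m=7`** (time-only smoothing over a
  ~55 ms window at 128 Hz).  `m` must be odd so same-padding is
  symmetric in time; `l ≤ n_channels`.
- **Near-pass-through initialisation**: `w = 1`, `b = 0`, `K` the
  uniform averaging kernel `1/(l·m)`.  An untrained EnK then perturbs
  its host network only mildly, which keeps the paired with/without
  comparison an honest test of what training makes of the layer.
- **Sliding-window reading of the artifact sum.**  Written literally,
  the artifact definition sums over all `i, j` and produces a single
  scalar; a scalar cannot enter the per-time-step sum `P_t + S_t + A_t`
  shape-consistently, so the windowed (convolutional) interpretation is
  adopted and stated bit-exactly (cross-correlation, zero same-padding,
  stride 1) so that an independent scalar-loop oracle can reproduce it.

## The network engine

No deep-learning framework is used: `enkit.nn` is a small, deliberately
dependency-free numpy engine with hand-derived backward passes
(im2col + BLAS matmul for convolutions), sized for desk-scale EEG
epochs.  It provides standard 2-D and depthwise convolutions, batch
normalisation (eps 1e−3, momentum 0.1, running statistics for
inference), ELU/ReLU/square/clamped-log activations, average and max
pooling (overlapping strides supported), inverted dropout, dense
layers, a recurrent-convolution layer, and Adam (β₁ 0.9, β₂ 0.999,
eps 1e−8).  Gradient correctness is enforced by finite-difference
tests; inference-mode forward passes are deterministic.

## Baseline architectures

Four classifiers are built from a declarative `ModelSpec`; input layout
is `(batch, 1, channels, samples)` and reshaping happens only at the
model boundary.

- **eegnet** — EEGNet-8,2: temporal convolution (F1 = 8 maps, kernel
  1×64, same padding, no bias), batch norm, depthwise spatial filter
  (C×1, depth 2), batch norm + ELU, average pool 1×4, dropout,
  separable convolution (depthwise 1×16 + pointwise to F2 = 16), batch
  norm + ELU, average pool 1×8, dropout, dense softmax head.
- **shallowconvnet** — temporal convolution (40 maps, 1×25), spatial
  convolution (C×1, no bias), batch norm, squaring nonlinearity,
  overlapping average pool (1×75, stride 1×15), log activation
  (clamped at 1e−6), dropout, dense head.
- **deepconvnet** — four convolutional blocks (25/50/100/200 maps,
  1×10 kernels, valid padding; the first block adds a C×1 spatial
  convolution), each with batch norm, ELU, max pool 1×3, dropout;
  dense head.  Valid convolutions and stacked pooling impose a minimum
  sample count (441 at default kernels); shorter inputs raise an error
  reporting that minimum.
- **rcnn** — an input temporal convolution (1×5, same), spatial
  convolution (C×1), then five recurrent-convolution blocks: each block
  applies a feed-forward 1×3 convolution once and a *shared* recurrent
  1×3 convolution three times (`h_i = relu(ff + W_r h_{i−1})`), batch
  norm after each block, max pool 1×2 between the first four blocks,
  global average pooling and a dense head.  The recurrent weights start
  at 0.1× Glorot scale so the unrolled map is contractive initially.
  The source description of this baseline is brief ("five recurrent
  convolution layers"); this unrolled weight-shared reading is our
  interpretation and is stated as such.

Filter counts for EEGNet and Shallow/DeepConvNet follow their original
publications; a `scale` multiplier shrinks filter counts (topology
unchanged) for fast tests.  When `enk_enabled`, the EnK layer is
spliced directly after the first convolution (`conv1`); it is
shape-preserving, so all downstream shapes are identical with and
without it, and the parameter count differs by exactly `2k' + l·m`.

## Synthetic EEG generator

No public simulation protocol exists for the task families the layer
targets, so the generator is built from standard EEG phenomenology.
Each epoch (default 8 channels × 128 samples at 128 Hz, one second) is
the sum of:

| component | default | emulates |
|---|---|---|
| 1/f background | exponent 1.0, RMS 1.0 (arbitrary units) | broadband EEG background; spectral shaping of white noise, analytically normalised |
| ERP bump | Gaussian σ 40 ms, amplitude 3.0, latency jittered ±20 ms | time-locked deflections (P300-like positive parietal at 300 ms; conflict-like negative frontal at 200 ms) |
| oscillatory burst | Hann-windowed sinusoid, 10 ± 1 Hz, random phase | band-limited rhythms (alpha for motor-imagery-like tasks) |
| blinks | Poisson rate 0.05/epoch, amplitude 8, σ 75 ms, fronto-polar | low-frequency, large-amplitude ocular artifacts |
| line noise | 50 Hz sinusoid, amplitude 0.2 | mains interference |

Class structure enters through per-class amplitude scales on the ERP or
the oscillation (e.g. the P300-like preset puts the parietal bump on
target epochs only), so labels depend on *time-dependent* features —
the regime the EnK exists for.  All random draws are taken regardless
of amplitude settings, so zeroing all amplitudes but one yields exactly
that component (strict additivity), and a fixed seed yields
bit-identical epoch sets.  Amplitudes are in arbitrary units: the EnK's
learned affine makes the pipeline scale-covariant, so absolute µV
calibration is not modelled.

What the generator does **not** emulate: volume conduction and realistic
spatial mixing, non-stationary drift across a session, inter-subject
variability, realistic artifact morphology, or the preprocessing
heterogeneity of public BCI datasets.  Passing tests on this data show
that the layer and pipeline behave as specified and that the layer can
exploit clean time-locked class structure; they do not establish
performance on real recordings.

## Training and evaluation protocol

- Stratified 60/20/20 train/validation/test split; validation and test
  sizes are floored per class, the remainder goes to train; every class
  must land in every partition or the split fails naming the class.
- Adam, learning rate 0.001, batch size 16 (configurable within 2–16),
  dropout 0.25 (configurable within 0.15–0.75), at most 200 training
  epochs, early stopping when validation loss has not improved for 20
  epochs, best-validation weights restored on stop.  Training minimises
  cross-entropy; with a strictly worsening validation loss from epoch 1
  the stopper halts at epoch `patience + 1`.
- Metrics: MSE between one-hot labels and softmax probabilities
  (averaged over epochs and classes) and F1 (positive-class F1 when
  binary, support-weighted mean of per-class F1 otherwise; a class
  absent from the test set scores 0 and raises a warning flag in the
  report).  MSE is computed on probabilities, not hard labels — the
  defining text leaves this open and the probability reading is the
  smoother, more informative choice.
- One master seed derives the split, initialisation, batch-order and
  dropout streams, so the EnK-on and EnK-off arms of `compare_enk` are
  exactly paired: same split indices, same initial host weights, same
  batch schedule, differing only in the presence of the layer.

## Grad-CAM

Maps target the EnK layer's output when the layer is enabled, else the
first convolution's output.  Feature-map weights are the spatial mean
of the class-logit gradient; the heat map is the rectified weighted sum,
max-normalised to [0, 1] (an all-zero map stays zero — normalisation
and resampling are not dictated by the Grad-CAM definition, so these
choices are fixed here).  For overlay the map is linearly interpolated
along time to the input's sample count and rendered behind the
per-channel line graph.  Difference maps are taken on the normalised
maps and not renormalised, so their range is [−1, 1].  The
time-locality measurement reports the fraction of total heat mass
inside the ERP window, defined as latency ± (2σ + jitter)
(200–400 ms for the P300-like preset, i.e. 20 % of the epoch); a
flat-in-time map scores exactly the window's duration fraction.

## Problem sizes

The bundled experiments run on one CPU at desk scale: the paired
P300-like experiment uses 400 epochs × 8 channels × 128 samples with
EEGNet-8,2 (protocol seed 7) and finishes in roughly two minutes; unit
and property tests use 20–40-epoch sets and scaled-down models.  These
sizes are the package's chosen study conditions for a self-contained,
reproducible demonstration.

## Known limitations

- The numpy engine is single-threaded BLAS-bound and not meant for
  full-size public BCI datasets; the architectures are faithful but not
  numerically identical to their original framework implementations
  (e.g. no max-norm weight constraints in EEGNet).
- The RCNN baseline is an interpretation of a brief description, as
  noted above.
- Synthetic data is favourable to the method by construction (clean,
  time-locked class structure); paired deltas on it demonstrate
  mechanism, not field performance.
- The `t = 0` boundary rule and the sliding-window artifact reading are
  reasoned choices where the defining equations are ambiguous; both are
  pinned by tests so any alternative reading would be a deliberate,
  visible change.
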
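# Methods

## The model

`segbrain` implements a compact encoder–decoder convolutional network for
pixel-label (semantic) segmentation of 2D T1-weighted, skull-stripped brain
MRI slices into four classes: background, cerebrospinal fluid (CSF), gray
matter (GM) and white matter (WM).

The stack has 31 layers in two encoder and two decoder blocks:

```
input (1 channel, zero-centered)
encoder1:  conv3x3(64) – BN – ReLU – conv3x3(64) – BN – ReLU – maxpool 2x2
encoder2:  conv3x3(64) – BN – ReLU – conv3x3(64) – BN – ReLU – maxpool 2x2
decoder2:  unpool 2x2 – conv3x3(64) – BN – ReLU – conv3x3(64) – BN – ReLU
decoder1:  unpool 2x2 – conv3x3(64) – BN – ReLU – conv3x3(4) – BN – ReLU
softmax (per pixel) – class-weighted cross-entropy
```

All convolutions are 3×3, stride 1, zero "same" padding.  Each 2×2,
stride-2 max pool memorizes the per-window argmax position; the decoder
unpool paired with it (encoder1↔decoder1, encoder2↔decoder2) scatters the
pooled values back to exactly those positions and fills the rest with
zeros, so upsampling preserves the spatial localization of strong features
instead of smearing them by interpolation.  At the default filter width of
64 the network has 225,420 trainable scalars (8 convolutions:
640 + 6×36,928 + 2,308; 8 batch norms: 7×128 + 8).

Ties in a pooling window go to the first (row-major) position, and
per-pixel argmax ties go to the lowest class index; both rules are fixed so
that index bookkeeping and predictions are bit-reproducible.

The layer arithmetic and all gradients are implemented directly in numpy.
Convolutions run as nine shifted contiguous copies feeding one batched
GEMM; the input gradient is the adjoint convolution (channel-transposed,
spatially flipped kernels), and the weight gradient is a batched GEMM
against the same shifted columns.  Batch-norm backward propagates through
the batch statistics (the full normalization Jacobian).  Correctness is
enforced by brute-force oracle tests on every primitive and by a central
finite-difference check of the end-to-end loss gradient.

## Training recipe

* **Loss** — class-weighted cross-entropy averaged over pixels:
  `L = −(1/N) Σ_p w[y_p] · log max(p_{y_p}, 1e−12)`.  The probability floor
  only guards the logarithm; gradients use the exact fused
  softmax/cross-entropy form `w[y]/N · (p − onehot(y))`.
* **Class weights** — median-frequency balancing by default:
  `w_c = median(freq)/freq_c`, computed over the training label maps;
  a uniform alternative is exposed.  Every class must be present, otherwise
  the weight is undefined and the run is rejected.
* **Optimizer** — stochastic gradient descent with momentum:
  `v ← μ·v − η·g`, `θ ← θ + v`, defaults η = 0.001, μ = 0.9, minibatch 8.
* **Augmentation** — on the fly per epoch: horizontal (X-axis) reflection
  with probability ½ and a rotation drawn uniformly from ±10° about the
  image center (bilinear for intensities, nearest-neighbour for labels,
  background fill outside the canvas).
* **Batch norm** — ε = 1e−5; running statistics updated by an exponential
  moving average with factor 0.1 (train mode); inference uses the running
  statistics and is rejected before any exist.
* **Initialization** — He (fan-in-scaled) normal for kernels, zero biases,
  γ = 1, β = 0, running stats (0, 1); fully determined by the seed.
* **Stopping** — fixed `max_epochs` plus early stop once the training loss
  has improved by less than 1e−4 for 10 consecutive epochs; the parameters
  returned are the best-by-training-loss snapshot.

A convergence caveat worth knowing: with the loss averaged per pixel, the
nominal rate η = 0.001 moves parameters very slowly — on the synthetic task
below, 40 epochs over 32 slices (160 updates) reach a held-out mean tissue
Dice of only ≈ 0.68, still improving.  Normalizing the loss per observation
instead (summing over pixels) multiplies the effective step by H·W and
destabilizes this architecture's BN+ReLU classification head (channels
saturate inactive and stop learning).  Users who want fast convergence at
pixel-mean normalization should raise the learning rate: η ≈ 0.05–0.8 fits
the synthetic task to Dice > 0.9 within a handful of epochs.  The package
deliberately keeps both the pixel-mean loss and the published default rate.

## The phantom generator

The built-in generator emulates a skull-stripped axial T1 slice as nested
ellipses: a dark background (intensity 0), a thin outer CSF band, a
cortical GM band, a WM interior, and `n_ventricles` small CSF ellipses
(default 2) inside the WM, mimicking lateral ventricles.  Default noise-free
class means are CSF 0.20, GM 0.50, WM 0.80 on a [0, 1] scale — the T1
ordering CSF < GM < WM.  The intensity model is

```
image = mean[label] × bias_field + N(0, σ²),  clipped to [0, 1]
```

with a single smooth Gaussian-bump multiplicative bias field spanning
1 ± `bias_amplitude` (default 0.10, a typical inhomogeneity magnitude) and
additive Gaussian noise σ = 0.03.  Ellipse centers, axes and orientation are
jittered per item (relative jitter 0.10), with per-item seeds derived as
master seed + index so any subset is reproducible.  The default canvas is
96×96 so a full training run fits on a desktop CPU; the full 208×176 slice
size is supported (both dimensions must divide 4 so the two pooling stages
invert cleanly).

What the phantom does *not* model: cortical folding, partial-volume mixing
at tissue boundaries, Rician noise statistics, anatomical asymmetry, or 3D
context.  Passing tests on phantoms therefore demonstrates that the
architecture, gradients, training loop and metrics behave correctly — not
that the trained weights transfer to real scans.  On real data the same
pipeline applies after slicing and padding (see `segbrain.io_data`).

With the defaults, background is the most frequent class (≈ 55% of pixels),
so median-frequency weighting is exercised non-trivially (background weight
< 1, thin-structure weights > 1).  Note that clipping at 0 truncates the
negative noise tail over the background, so the *observed* background mean
is slightly positive for σ > 0; the noise-free background intensity is
exactly 0.

## Evaluation metrics

For a predicted/true label-map pair the report contains, per class
(one-vs-rest masks) and in aggregate:

* **Dice** `2|x∩y|/(|x|+|y|)` and **Jaccard/IoU** `|x∩y|/|x∪y|`, linked by
  `J = D/(2−D)`; both defined as 1 when both masks are empty ("nothing to
  find, nothing found").  Headline means average the three tissue classes
  (CSF, GM, WM), excluding background.
* **Confusion-matrix statistics** — global accuracy (trace/total),
  per-class accuracy (recall, diag/row sum), per-class IoU
  (diag/(row+col−diag)), their unweighted means over classes present, and
  the frequency-weighted IoU.
* **MSE** between the 0–255 gray renderings of the two label maps, with
  classes mapped to equally spaced levels {0, 85, 170, 255}.  The gray
  levels are a rendering convention (config-overridable), so MSE values are
  only comparable under the same mapping.
* **Boundary-F1 (BF)** — precision/recall of boundary pixels matched within
  a Euclidean tolerance (default 0.75% of the image diagonal, at least
  1 pixel), combined as 2PR/(P+R).  Boundaries are inner boundaries
  (4-connectivity), with the image border counting as outside.

Degenerate cases are pinned down explicitly: both-empty masks score 1 for
Dice/Jaccard/BF; a missing boundary on one side only scores 0; an empty
confusion matrix is rejected; mean statistics skip classes absent from the
ground truth.

## Problem sizes used by the self-checks

The acceptance script and test suite exercise: oracle equivalence on 100
random small instances per primitive; a central finite-difference gradient
check on a width-4 network with 8×8 double-precision inputs (coordinates
where both analytic and numeric values are below 1e−8 count as agreeing —
conv biases feeding straight into batch norm have an exactly zero
gradient); and one full-width training run of 32×(96×96) phantoms for up to
40 epochs with the default recipe, evaluated on 8 held-out phantoms.  These
sizes keep a complete run on a single CPU core in the tens of minutes.

## Design choices that were genuinely open

* **Axis conventions** — tensors are (batch, channel, height, width)
  throughout; volumes keep their on-disk axis order and slicing is always
  explicit, because source orientation metadata is unreliable.
* **Checkpoints** — a single `.npz` mapping layer names to arrays plus a
  JSON header with an architecture hash; loading verifies the hash so a
  checkpoint cannot silently deserialize into a different stack.
* **Best-by-loss selection** rather than last-epoch parameters: cheap
  insurance against a late noisy step, at the cost of one parameter copy
  per improving epoch.
* **Filter-width switch** — the architecture builder takes the width as a
  parameter (default 64).  Reduced widths train in seconds and are used by
  the unit tests; the layer list and pairings are identical at any width.

## Known limitations

Single-channel 2D slices only (no 3D context, no multi-contrast input);
the original 13-layer-per-side VGG16 encoder variant is out of scope, as
are dropout and skip-concatenation decoders; training is single-threaded
CPU numpy — practical for the phantom task and for fine-tuning small
slices, not for large-scale training; and the phantom realism limits noted
above apply to every reported number.
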
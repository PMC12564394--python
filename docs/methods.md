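# Methods

This note documents the models, numerical choices and design decisions
behind `pneumocaps`, and what its tests do and do not demonstrate.

## Preprocessing

Each radiograph passes through a fixed chain: bilinear resize to the model
input size → division by 255 into [0, 1] → Gaussian denoising → CLAHE →
gamma correction → replication of the gray channel to the 3 channels the
network input expects.

- **Resize.** Half-pixel-centred bilinear sampling (`map_coordinates`,
  order 1, edge clamping): output pixel (r, c) samples the input at
  ((r+0.5)·H/H′−0.5, (c+0.5)·W/W′−0.5). The convention is stated because
  the unit tests verify against a per-pixel evaluation of the textbook
  bilinear formula with the same convention.
- **Denoising.** Convolution with an explicitly constructed, normalized
  Gaussian window (default 3×3, σ = 1.0) with reflected borders, so a
  constant image is a fixed point and interior mass is conserved. The
  kernel size is a choice — the smallest standard denoising window —
  since only the filter family is dictated by the pipeline design.
- **CLAHE.** The normalized image is quantized to 8 bits (the algorithm
  is histogram-based), equalized per tile with contrast limiting and
  bilinear blending of the tile mappings (scikit-image's
  `equalize_adapthist`), and rescaled to [0, 1]. The clip limit is
  expressed in 256-bin histogram units: the default 2.0 caps every bin at
  twice the uniform tile count, a mild enhancement. Tile grid default is
  8×8. **Caveat at low resolution:** tile kernels must stay large relative
  to the anatomy. At 224 px, an 8×8 grid gives 28-px kernels; at the
  64-px toy scale the equivalent kernels come from a 2×2 grid. Using an
  8×8 grid at 64 px produces 8-px kernels whose near-degenerate local
  histograms equalize away exactly the lung-opacity contrast the
  classifier should use — measured on the generator, the mean
  pneumonia-minus-normal lung intensity difference changes sign. The toy
  test conditions therefore use `clahe_tile_grid=(2, 2)` at 64 px.
- **Gamma.** out = in^γ with γ = 1.2 by default (mild deepening of dark
  tones; γ = 1 disables). The exponent is a configurable choice, not a
  constraint of the pipeline design.

Every stage is pure; `normalize01` refuses floating input so the 0–1
rescaling cannot be applied twice.

## The capsule network

Implemented entirely in NumPy (forward and backward), in NHWC layout:

1. 3×3 convolutional stem, 'same' padding, ReLU (kernel size is fixed by
   the reference architecture's parameter accounting: 1792 = 3·3·3·64+64);
2. 2×2 max-pool, then optional dropout (inverted scaling, off at rate 0);
3. PrimaryCaps: 3×3 convolution, stride 2, 'same' padding
   (TensorFlow-style asymmetric pad), output channels = types·d_p,
   reshaped into position-major capsules and squashed;
4. DigitCaps: per-pair transform matrices W_ij (no bias — the reference
   count 25,690,112 = 100,352·2·8·16 matches transforms only) and
   routing-by-agreement with logits initialized at zero, softmax over
   output capsules, and the agreement update skipped after the last
   iteration;
5. class scores = capsule lengths; prediction = argmax (ties resolve to
   the lower class index).

**Squash.** v = (‖s‖²/(1+‖s‖²))·s/‖s‖ with an ε = 1e-12 guard, so 0 → 0
and norms satisfy 0 ≤ ‖v‖ < 1, strictly increasing in ‖s‖, direction
preserved. Its exact vector-Jacobian product is used in the backward
pass: with n = ‖s‖, a(n) = n/(1+n²), ds = a·dv + a′(n)(ŝ·dv)ŝ,
a′(n) = (1−n²)/(1+n²)².

**Backward pass through routing.** The converged coupling coefficients
c_ij are treated as constants: gradients flow through the final weighted
sum s_j = Σ c_ij û_{j|i} and both squash applications, but not through the
iterative refinement of c. This is the simplification most published
capsule-network implementations use; empirically the full-model gradients
agree with central finite differences to ~1e-5 relative error at r = 2
(tested), and training converges on the toy task in a handful of epochs.
The *forward* routing is exact and is verified against a literal
loop-and-sum transcription of the algorithm on 100 random instances
(tolerance 1e-6).

**Parameter accounting.** Closed forms — stem k²·c_in·F + F, PrimaryCaps
k²·F·(types·d_p) + types·d_p, DigitCaps N·classes·d_p·d_o — are checked
against the sizes of the actually allocated weight arrays for arbitrary
valid configurations, and reproduce the reference totals
(1,792 / 147,712 / 25,690,112; 25,839,616).

**Initialization.** He-scaled normal for both convolutions, N(0, 0.01)
for the routing transforms so the initial capsule sums do not saturate
the squash; seeded and reproducible.

**Margin loss.** Σ_k T_k max(0, 0.9−‖v_k‖)² + 0.5(1−T_k)max(0, ‖v_k‖−0.1)²
averaged over the batch; zero exactly when the true-class length ≥ 0.9
and all others ≤ 0.1.

## Training

Adam (β = 0.9/0.999, ε = 1e-8) at learning rate 1e-4 by default, batch
size 16, up to 30 epochs, early stopping when validation accuracy has not
improved for 5 consecutive epochs (the stopping criterion's patience is a
package choice; only the metric — validation accuracy — and the use of
early stopping are dictated by the training design). The returned weights
are the best-epoch snapshot. Splits are stratified per class with
largest-remainder rounding (fractions preserved within ±1 sample per
class), default 70/15/15 — at 5,863 images this yields a test set of
879–881, matching a reported 880-image test set at 15%. Runs are
deterministic under fixed seeds (single-threaded NumPy, seeded shuffling
and dropout).

## Hyperparameter search

Search space: learning rate log-uniform on [1e-5, 1e-3]; stem filters
∈ {32, 64, 128}; dropout uniform on [0, 0.5]; primary-capsule dimension
∈ {8, 16, 32} (class capsules stay 16-dimensional); batch size
∈ {8, 16, 32}. Trials run at reduced fidelity — 112-px inputs, a
stratified 40% subsample of the training data drawn once per study so
trials are comparable, at most 8 epochs — under budgets of 100 trials or
8 hours, whichever binds first. The trial objective is the best (not
last) epoch validation accuracy, the conservative reading when epochs
are few.

The suggestion engine is a Tree-structured-Parzen-Estimator-style
sampler written on `scipy.stats.gaussian_kde`: after 10 random start-up
trials the history is split at the top-25% objective quantile; continuous
parameters are proposed by maximizing the good/bad density ratio over
candidates drawn from the good model (learning rate in log10 space),
categorical parameters by sampling proportionally to the smoothed
good/bad probability ratio. A uniform random sampler is available behind
`sampler="random"`. Pruning follows the median rule: after a 2-epoch
warm-up, a trial is cut iff its intermediate validation accuracy is
strictly below the median of peer intermediates at the same epoch (ties
continue; no pruning without peers).

## Metrics

Accuracy, sensitivity, specificity, PPV, NPV, FPR, FNR, F1 and MCC are
computed from their closed forms on TP/TN/FP/FN counts with the pneumonia
class positive. A zero denominator yields NaN plus the metric's name in
the report's `undefined` list — never a silent zero. ROC AUC (trapezoidal
= pairwise concordance with half credit for ties) and average precision
delegate to scikit-learn and are cross-checked in the tests against a
brute-force pairwise-concordance oracle and a hand-computed
precision-recall sweep. `confusion_from_summary` reconstructs a matrix
from a reported (total, FP, FN, sensitivity) summary by solving
TP/(TP+FN) = sensitivity for integer TP; reconstruction from 880/35/8/
0.987539 gives TP = 634, TN = 203, from which all nine scalar metrics
reproduce their published six-decimal values — an internal-consistency
check the acceptance suite performs.

## Explainability

Grad-CAM targets the PrimaryCaps convolution's pre-reshape feature maps
(the network's last convolutional computation; the class-capsule layer is
not convolutional). The class score for backpropagation is the target
capsule's length. Channel weights are the spatial means of
∂score/∂feature-map; the map is ReLU(Σ_k w_k A_k), min-max normalized,
bilinearly upsampled to the input size and re-normalized so the stored
heatmap peaks at exactly 1 (an identically-zero raw map is flagged
instead). The localization statistic thresholds the heatmap at τ
(default 0.5, configurable) and reports the fraction of supra-threshold
pixels inside vs outside a binary lung mask; zero supra-threshold pixels
yield a flagged empty result rather than a number.

## The synthetic generator

Each image is an 8-bit grayscale scene: dark background, a bright thorax
ellipse, two darker elliptical lung fields (the returned ground-truth
mask), sinusoidal rib-like banding confined to the thorax wall, and
additive Gaussian noise (default σ = 0.02 on the [0, 1] scale ≈ 5 gray
levels). Pneumonia images add 1–4 blurred Gaussian opacities of peak
amplitude 70 gray levels and radius 1/16–1/8 of the frame; opacity
centres are sampled from the lung mask eroded by ~0.75 of the blob radius
so each consolidation lies wholly in parenchyma, which is what makes the
ground-truth mask a fair reference for localization tests. Generation is
byte-deterministic given the spec (seed included); default frame 256 px
(96 px in the test conditions, for speed).

What the generator does *not* emulate: real anatomy (mediastinum, heart
shadow, diaphragm), ribs crossing the lung fields, projection and
positioning variability, scanner/exposure differences, interstitial and
atypical pneumonia patterns, and label noise. Passing the synthetic
end-to-end tests therefore shows that the pipeline's machinery — the
preprocessing, the capsule classifier and its optimizer, the metric
suite, the Grad-CAM chain — is correct and that the classifier can learn
a localized brightness cue; it says nothing about clinical performance on
real radiographs.

## Test-scale choices

The test suite and the acceptance script run a deliberately small version
of everything: 420 synthetic images at 96 px (300 train / 60 val /
60 test), a toy network (64-px input, 8 stem filters, 4 primary-capsule
types of dimension 4, 8-dimensional class capsules, 3 routing
iterations), learning rate 5e-4 for the shorter schedule, up to 10
epochs; the hyperparameter study runs 5 trials at 32 px on a 40%
subsample with a 6-epoch cap over a reduced space (filters {4, 8},
capsule dimension {2, 4}, batch {8, 16}). At these sizes a full suite run
and the acceptance script each take well under a minute on a single CPU.
The full-resolution reference configuration is exercised where it is
cheap — parameter accounting builds the real 25.8M-parameter weight
arrays — but not trained.

## Known limitations

- The routing backward pass is approximate (constant couplings), so
  training dynamics can differ slightly from a fully differentiated
  implementation; forward outputs and all reported scores are exact.
- The NumPy implementation is CPU-bound and single-threaded; the
  reference 224-px architecture is buildable and runnable but impractical
  to train here.
- Capsule lengths are scores, not calibrated probabilities;
  `predict_proba` normalizes them to a simplex for API compatibility
  without any calibration claim.
- The TPE-style sampler models parameters independently (no joint
  density), adequate for the five-dimensional space it serves.
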
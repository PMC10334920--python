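# Methods

This note records the models implemented in `dermatone`, the numerical
choices behind them, and what the synthetic test fixtures do and do not
emulate. Every number quoted in the README is produced by the test suite or
by `scripts/acceptance.py`; this note makes no empirical claims beyond those.

## Problem setting

Dermatology image banks used to train lesion classifiers are dominated by
light skin tones. The package implements a pipeline that (1) quantifies the
tone composition of an image bank, (2) synthesizes darker-skin counterparts
of light-skin lesion images, (3) scores the realism and content preservation
of the synthesized images, (4) analyzes human-rater studies of those images,
and (5) measures the effect of the synthesized images as training
augmentation for a malignant/benign classifier.

## Skin-tone quantification (`skin_tone`)

Skin tone is summarized by the individual typology angle (ITA), computed in
CIELAB (D65 white point, conversion via `skimage.color.rgb2lab`):

    ITA = atan((L* - 50) / b*) * 180 / pi

Per image, the median L* and median b* over the (optionally masked) skin
pixels are used, which is robust to lesion pixels and specular highlights.
Categories follow the six-band convention: very light (ITA > 55), light
(41, 55], intermediate (28, 41], tan (10, 28], brown (-30, 10], dark
(<= -30). Intervals are half-open with inclusive upper bounds; b* = 0 maps
to +/-90 degrees by the sign of L* - 50.

## Feature extractor (`features`)

Style transfer and deep blending need a differentiable convolutional feature
extractor. No GPU deep-learning framework is assumed: the package implements
a NumPy convolutional network (3x3 same-padding convolutions + ReLU, 2x2
average pooling) with exact manual backpropagation. Two descriptors are
provided: a VGG-19-shaped one (16 convolutions, 5 poolings) whose weights
must be supplied by the user as an HDF5 file, and a small fixture descriptor
(conv1_1 -> pool1 -> conv2_1 -> pool2 -> conv3_1, channels 8/16/16) with
seeded He-initialized weights and zero biases used throughout the tests.
Input gradients are verified against central finite differences to relative
1e-5; random seeded features are a standard stand-in for pretrained ones
when only the optimization machinery, not perceptual quality, is under test.

## Style transfer (`generation.synthesize_st`)

Gatys-style iterative synthesis. With feature maps F (C channels, N = H*W
positions) and Gram matrices G = F F^T / (C N):

- content loss: sum over content layers of w * 0.5 * ||F_x - F_c||^2
- style loss: sum over style layers of w * ||G_x - G_s||^2
- total = alpha * content + beta * style (defaults alpha = 1, beta = 1000)

Optimization is Adam (lr 0.02) from seeded uniform noise (or the content
image), pixels clipped to [0, 1] after each step; the best iterate by total
loss is returned along with a per-iteration trace. All randomness flows from
a single integer seed, so reruns are bit-identical.

## Deep blending (`generation.synthesize_db`)

A lesion region (binary mask) from a content image is composited into a
style image and the blend is optimized under three losses: the
Poisson-gradient loss — mean squared difference between the 4-neighbor
Laplacian (replicate boundary) of the blend and of the composite, evaluated
on the blend region — plus the same content and style losses as above.
Optimization is confined to the mask dilated by a disk (default radius 5);
pixels outside are pinned to the style image, which guarantees locality.
Blending runs in two rounds: round 2 re-blends the round-1 output (its
gradient/content targets are rebuilt from that output), which makes the
round-2 total provably no worse than round 1. The Laplacian adjoint used in
the gradient is exact (verified as an inner-product identity to 1e-12).

## Quality metrics (`quality`)

- **SSIM** via `skimage.metrics.structural_similarity` on BT.601 luminance
  (11x11 Gaussian window, sigma 1.5, K1 = 0.01, K2 = 0.03).
- **BRISQUE features** are implemented from the definition: MSCN
  coefficients (I - mu) / (sigma + 1) on 0-255 luminance with a 7x7 Gaussian
  window (sigma 7/6); a generalized Gaussian (GGD) fit to the MSCN
  distribution and asymmetric GGD fits to the four orientation products,
  giving 18 features per scale at 2 scales (2x2 mean downsampling) = 36.
  Fits use moment matching with a dense gamma-ratio grid (0.2-10, step
  0.001).
- **Scoring**: the reference BRISQUE regressor is trained on a proprietary
  opinion database and is not shipped; instead `BrisqueDistanceScorer`
  (sklearn-style `fit`/`score_image`) computes the Mahalanobis distance of
  an image's 36 features to a pristine corpus (regularized covariance
  pseudo-inverse). Higher = more distorted. A `LinearBrisqueScorer` accepts
  user-supplied weights. Scores are min-max normalized per batch.

## Rater-study statistics (`evalstats`)

- Exact binomial (Clopper-Pearson) intervals via Beta quantiles
  (`scipy.stats.beta.ppf`), with the conventional closed forms at x = 0 and
  x = n.
- Visual-Turing-test metrics: FPR (generated judged real), TPR (real judged
  real), and vote-weighted overall accuracy, each with exact CIs.
- Per-group diagnosis recall and row-normalized 10-disease confusion
  matrices.
- OLS significance via `statsmodels` (rank-deficiency reported with the
  collinear column names).
- AUC via `sklearn.metrics.roc_auc_score`; paired AUC comparison by
  DeLong's test using midrank placement values and the placement covariance,
  two-sided normal p-value. Degenerate (identical-score) comparisons return
  z = 0, p = 1.

## Classifier and augmentation regimes (`classifier`)

Training sets are built under four regimes: (a) originals only,
(b) originals + generated darker-tone counterparts (3 styles per eligible
light/intermediate image), (c) originals + geometric transforms (h/v flips,
rotations 90/180/270 with reflective fill, Gaussian noise sd 0.02), and
(d) both. Regime sizes are exact: a = n, b = n + 3 n_eligible,
c = n (1 + |ops|), d = n + 3 n_eligible + n |ops|.

`LesionClassifier` is a scikit-learn estimator: a frozen convolutional
backbone up to the last pooling stage, then a trainable 3x3 convolution,
global average pooling, and a 2-way softmax. Frozen features are
standardized per channel with statistics frozen at fit time (this
conditions the head optimization independently of backbone activation
scale). Training is Adam (default 30 epochs, lr 0.001, batch 16) with a
plateau schedule: the lr is halved (floor 1e-6) when validation accuracy —
or training loss, if no validation set is given — fails to improve for 5
consecutive epochs. The 80/20 split is class-stratified by default.
Evaluation reports accuracy with an exact binomial CI and AUC with a
DeLong-variance CI, and persists per-case scores for paired tests.

## Synthetic fixtures (`fixtures`): what they emulate and what they don't

Fixture images are procedurally generated skin patches: a uniform
background whose CIELAB values are solved so that the ITA hits a requested
target (at fixed a* = 10, b* = 15), an elliptical pigmented lesion with an
anisotropic Gaussian falloff, and seeded Gaussian texture noise. Malignant
fixtures get larger, more irregular, darker lesions than benign ones, so
class is encoded in lesion geometry/pigment and is independent of skin
tone. Rater tables and diagnosis tables are simulated from Bernoulli rates,
or reconstructed exactly from published marginal counts.

Fixtures emulate: tone-controlled backgrounds, lesion/background structure,
separable class signal, manifest plumbing, and the train-light/test-dark
distribution shift. They do not emulate: real lesion morphology, camera
noise, hair/rulers/artifacts, or perceptual realism — so absolute quality
scores and absolute classifier accuracies on fixtures are not comparable to
real-data values, and the benchmark claim is directional only (regime b
beats regime a under tone shift).

## Numerical choices

- All synthesis, training, and simulation randomness flows from integer
  seeds through `numpy.random.default_rng`; reruns are bit-identical on the
  same platform.
- Losses and gradients are computed in float64.
- Adam is the only optimizer; L-BFGS is avoided to keep determinism simple.
- GGD/AGGD fits use moment matching (not MLE) as in the original BRISQUE
  formulation; the tests verify agreement with a grid MLE within 5%.
- Image I/O quantizes to 8-bit PNG; round trips are exact to 0.5/255.

## Limitations

- The fixture backbone is random-seeded, not pretrained; it tests the
  machinery, not perceptual transfer quality.
- BRISQUE scores here are corpus-relative distances, not opinion-calibrated
  quality scores.
- The tone-shift benchmark is run at desk scale (32x32 images, tens of
  images, 10 seeds); it demonstrates ordering, not effect size.
- Deep blending assumes lesion masks are available; no segmentation is
  provided.
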
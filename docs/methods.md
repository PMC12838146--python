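# Methods

## Model

The classifier combines two feature branches extracted from the same 2-D
grayscale image.

**Radiomics branch.**  Features are computed inside a binary ROI mask (the
whole image when no mask is given): 17 first-order intensity statistics
(population-convention moments; skewness and excess kurtosis of a constant
ROI are defined as 0, histogram entropy on 32 equal-width bins), 8 shape
descriptors of the largest connected mask component (area as pixel count,
perimeter by the weighted boundary-segment estimator, circularity 4πA/P²,
eccentricity and axis lengths from the second-moment ellipse, extent,
solidity — all translation-invariant; centroids are deliberately excluded),
6 co-occurrence features per distance (contrast, dissimilarity, energy,
homogeneity, correlation, entropy) and 5 run-length features (SRE, LRE, GLN,
RLN, RP).  Intensities are discretized to 32 equal-width levels between the
ROI minimum and maximum (fixed-bin-count; a constant ROI maps to level 0).
Co-occurrence matrices are symmetric (pairs counted in both directions),
summed over the four standard directions and normalized to unit mass; both
pixels of a pair must lie inside the ROI.  Runs are maximal equal-level
stretches fully inside the ROI, features averaged over directions.  The
co-occurrence correlation feature of zero-variance marginals is defined as 0.
The 48-column table is z-scored with training-split statistics and reduced by
L1-penalized multinomial logistic regression: the penalty is chosen by
5-fold cross-validated deviance over a 9-point log-spaced path (ties resolve
toward the stronger penalty, i.e. the sparser model), features are ranked by
the largest absolute coefficient across classes, and the top k = min(100,
n_features) kept; if fewer have nonzero coefficients, all nonzero ones are
kept and the reduction is recorded.

**Deep branch.**  A four-block strided CNN (3×3 convolutions, stride 2,
batch norm, ReLU, channel widths native_dim/8 … native_dim, global average
pooling) maps the image to a native_dim-vector, which a trainable linear
layer projects to the unified dimension d.  The branch is trained end to end;
no pretraining is involved.  The encoder is pluggable: anything mapping
(B, H, W) images to (B, native_dim) satisfies the contract.

**Fusion (anti-cross-attention).**  Both branches are row-L2-normalized
(`Rp = Norm(Wrp R + brp)`, `Fn = Norm(F)`).  Per sample, the bilinear
interaction `M_b = (r_p W)^T f_n` (rank 1 by construction) is batch-normalized
per (i, j) channel, softmaxed along the deep-feature axis into `A`, inverted
(`A_inv = 1 − A`), and aggregated by column sum divided by d so the weights
lie in [0, 1] (for any valid map their sum is exactly d − 1).  A learnable
sigmoid-squashed gate g (scalar by default) forms `w = g·a + (1 − g)`; with g
strictly inside (0, 1) the derivative of `Fatt = Fn ⊙ w` w.r.t. `Fn` never
vanishes, which is the point of the residual term.  The fused vector is
`BN(Concat(Rp, Fatt))` of width 2d.  The ablation baseline replaces all of
this by `BN(Concat(Rp, Fn))`.

**Decorrelation.**  Each branch's normalized features pass through a
one-hidden-layer MLP (width d, SiLU) into a shared d-dimensional latent
space.  The projector outputs are row-L2-normalized: the cross-covariance
penalty on its own has a trivial minimizer (deflate the latent scale), so the
views are pinned to the unit sphere, which makes the loss scale-free and the
regularizer non-degenerate.  Views are centered per feature dimension over
the batch; `L_dec = ||C12||²_F` with `C12 = H1'^T H2'/(B−1)`.  The within-view
blocks C11, C22 (+εI, ε = 1e−4) are constructed for diagnostics and tests but
do not enter the loss.  The loss is computed per mini-batch.  Gradients
propagate through both branches (not only the MLPs).  The weight follows
`α = α_max · epoch / n_epochs` stepped per epoch, α_max default 0.2.

**Head.**  The spline head batch-normalizes the fused vector (gain
initialised at 0.5 so ~95% of inputs start inside the spline support) and
applies one KAN layer: per edge, a cubic B-spline expansion on a uniform
[−1, 1] grid with 5 interior intervals (8 basis functions, Cox–de Boor
recursion; inputs clamped to the grid; outside the support only the smooth
base path x·sigmoid(x) has gradient) plus a learned base weight and per-edge
spline scale.  Spline coefficients start as small noise, so the head is
near-linear at initialisation.  Grid refinement/update is not implemented.
A plain linear head replaces it in the ablation configurations.

## Training protocol

Adam (coupled L2 weight decay), batch size 32 (batches of fewer than 2
samples are skipped — batch statistics), cross-entropy plus the scheduled
decorrelation term.  The protocol defaults mirror the usual recipe for this
model family (200 epochs, lr 1e−4, weight decay 1e−5, 8:2 stratified
train/test split); the desk-scale experiments in the tests and acceptance
script instead train from scratch for 30 epochs at lr 1e−3 with d = 64 and
native_dim = 64 — chosen as the package's own scaled-down configuration
(the protocol's d = 512 with a pretrained transformer encoder is out of
scope).  10% of the training split is held out internally for early stopping
on validation AUC (patience 20); the test split never touches model
selection.  Augmentation (horizontal flip p = 0.5, rotation ±15°, scale
0.8–1.2, brightness/contrast jitter ±10%, one combined affine resampling)
applies to the encoder branch only; radiomic features are extracted once from
the unaugmented images — recomputing co-occurrence statistics per augmented
view would dominate the loop, and the ROI statistics are meant to describe
the native lesion.  Feature standardization and L1 selection are fitted on
the training portion excluding the validation holdout.  One seed drives
everything (init, shuffling, augmentation, splits) through spawned
substreams; two runs with the same seed are bit-identical.

## Synthetic data

Each sample is a 64×64 (configurable ≥16) grayscale image with one
elliptical lesion.  Three signal channels are separately tunable, each in
units of the latent standard deviation (effect = 1 places adjacent class
means 1 sd apart):

* **texture** — the lesion interior is thresholded band-pass-filtered noise;
  the characteristic period scales as `4·exp(0.18·x_tex)` px (clipped to
  [2, 12]).  The binarized pattern is split 50/50 at the median, so interior
  mean and variance carry no label information: the signal is second-order
  only, visible to co-occurrence/run-length statistics but not to first-order
  ones, and (empirically) not to a randomly initialised CNN.
* **shape** — the ellipse semi-axes scale oppositely with `x_shp`
  (±8%/latent-sd), moving eccentricity and axis lengths.
* **context** — a background sine grating whose orientation follows
  `1.2·tanh(0.45·x_ctx)` rad (≈31°/latent-sd near zero, saturating at ±69° so
  orientations never wrap the 180° period and remain distinguishable under
  the ±15° rotation augmentation), plus a lesion-centre offset
  `0.06·n·tanh(0.5·x_ctx)`.  Both are global cues invisible to within-ROI
  radiomics but learnable by the encoder.

Texture and context latents share a common standard-normal factor:
`t = √ρ·z + √(1−ρ)·u`, `c = √ρ·z + √(1−ρ)·v`, so their correlation equals
the `redundancy` parameter ρ exactly.  Additive Gaussian noise (default sd
0.05 gray levels) is applied before clipping to [0, 1]; images are stored as
8-bit PNGs with 0/255 mask PNGs and a CSV manifest.

What the generator does **not** emulate: speckle or any acquisition physics,
multi-lesion images, anisotropic spacing, annotation noise, class imbalance,
or domain shift between train and test.  Passing end-to-end tests therefore
demonstrates that the architecture recovers planted multimodal signal under
controlled redundancy — not clinical performance.

## Study conditions for the end-to-end experiments

3 classes, 200 samples/class, 64×64, redundancy 0.3, "moderate" effect
sizes 1.0 and "strong" 3.0 (fixed before any experiment was run), seeds
0/1/2, 30 epochs.  Cross-correlation between the latent views is read out on
a large (600-sample) freshly generated draw from the same distribution: the
mean |correlation| estimator has a sampling-noise floor of ≈√(2/π)/√(B−1)
(≈0.07 at 120 test samples), which would mask the effect being measured;
600 samples lower the floor to ≈0.033.

## Numerical choices

* Equal-width quantization assigns the ROI maximum to the top level;
  half-open bins elsewhere.
* L2 normalization guards with ε = 1e−12 and returns all-zero rows unchanged.
* Batch-norm: momentum 0.1, ε = 1e−5, biased batch variance for both
  normalization and running statistics; training mode requires ≥2 samples
  per channel, evaluation uses running statistics (so evaluation is
  deterministic and permutation-equivariant).
* Attention softmax subtracts the row maximum before exponentiation.
* Undefined metric ratios (e.g. specificity with no negatives) return NaN
  flags, never exceptions; AUC of a single-class problem is NaN.
* Multi-class sensitivity/specificity/AUC are macro one-vs-rest averages;
  binary problems use the positive-class (class 1) convention, matching how
  binary clinical tables are reported.
* Non-finite training loss aborts with a diagnostic rather than continuing.

## Known limitations

The trainable stack runs on an in-package reverse-mode autodiff engine over
NumPy, adequate for the desk-scale encoder sizes used here but not for large
backbones; no GPU path exists.  GLSZM/NGTDM/GLDM feature families are not
implemented (extraction is pluggable).  Wavelet/LoG-filtered features, 3-D
inputs, DICOM and grid refinement for the spline head are out of scope.

At desk scale the accuracy differences between ablation arms are small
relative to seed-to-seed variation (roughly one or two test images per seed);
the ablation ladder controls for this by sharing splits and seeds across
arms, but single-seed comparisons should not be over-interpreted.  Two
scale-dependent effects recur in the end-to-end experiments: the spline
head's extra capacity costs a little accuracy relative to a linear head when
training a few hundred samples from scratch, and the decorrelation loss only
pays off in accuracy when the planted cross-modal redundancy is high (its
direct effect — lower held-out cross-correlation between the latent views —
is measurable already at low redundancy).  Neither observation contradicts
the architecture's design intent; both simply mark where a scaled-down,
from-scratch regime differs from training on top of large pretrained
encoders.
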
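# Methods

## Pixel-level discriminant bank

Each pixel-labeled diseased image yields one two-class linear discriminant
over raw RGB pixel triples (no neighborhood context): diseased pixels
(mask = 1) versus normal pixels (mask = 0) inside the valid imaging field.
The rule is the plug-in Gaussian classifier with shared covariance,

    w  = Σ⁻¹ (μ₁ − μ₀)
    x diseased  ⇔  wᵀx > ½ wᵀ(μ₁ + μ₀) − log(π₁/π₀),

with class means μ₁, μ₀ over the masked pixel populations, pooled
within-class covariance Σ (scatter matrices divided by n₁ + n₂ − 2) and
empirical priors π₁ = n₁/(n₁ + n₀).  Exact ties on the decision boundary
resolve to the normal class, the conservative call.

Numerical conditioning: saturated or hand-drawn constant-color masks make
Σ singular, so a ridge ε·I with ε = 10⁻⁶ · (tr Σ / 3 + 1) is always added
before the solve.  The `+ 1` keeps ε positive even for an exactly-zero
covariance.  The ridge is six orders of magnitude below the signal and
does not move the boundary on any non-degenerate input; an exact-equality
oracle test against an independently coded plug-in classifier passes with
the ridge applied on both routes.

The models of a bank are applied independently; bank order is fixed at
build time and preserved in serialization because the feature layout
depends on it.

## Valid-field preprocessing

The peripheral black border carries no tissue signal.  A pixel is border
iff all three RGB values are ≤ 10 **and** it is 8-connected to an image
corner through equally dark pixels (threshold + flood fill).  Dark pixels
interior to the field (lumen shadows) stay valid.  Border pixels are
excluded from discriminant training, ROI prediction and every feature fit.

## PDF-parameter features

For bank model k, the ROI is predicted on the RGB raster (the
discriminants are RGB-trained; only the fitted intensities use the chosen
color space).  Per channel, a density family is fitted by closed-form
maximum likelihood:

| family      | estimate                              | params/channel |
|-------------|---------------------------------------|----------------|
| normal      | μ̂ = x̄, σ̂ = √(Σ(x−x̄)²/n)            | 2              |
| rayleigh    | σ̂ = √(Σx²/2n)                         | 1              |
| exponential | scale = mean                           | 1              |

The normal σ̂ uses the n-denominator (the MLE, not the unbiased
estimator).  Rayleigh and exponential have nonnegative support and are
therefore fitted to |x|; this is a no-op on intensity channels and keeps
the scale well defined on signed opponent channels (YIQ I/Q, LAB a*/b*).
A model that fires on no pixel contributes an all-zero parameter block —
distinguishable from any real fit, since a fitted σ is positive almost
surely — so the feature length M × C × p is invariant.

Color spaces follow the standard colorimetric transforms (ITU-R BT.601
for YIQ and YCbCr, D65 sRGB for CIELAB, hexcone HSV, naive complement
CMYK) and are fitted on their native scales (H ∈ [0,1), L ∈ [0,100], …);
the downstream SVMs standardize per feature, so the scale choice does not
affect classification.

Ablation variants are provided for comparison experiments: ROI pixel
counts (length M), order statistics (mean/median/mode/sd per channel; the
mode is the most frequent exact value with ties to the smallest, which on
8-bit input is the most frequent intensity), and whole-image fits (one fit
per channel over the entire valid field, no ROI).

## Hierarchical SVM cascade

Seven binary soft-margin SVMs with Gaussian RBF kernel
K(x,z) = exp(−‖x−z‖²/2σ²):

* level 1 — gate `N|~N`, trained on all images;
* level 2 — `B|~B`, `T|~T`, `U|~U`, trained on diseased images only (the
  normal class is consumed by the gate);
* level 3 — pairwise tie-breaks `B|T`, `B|U`, `T|U`, trained on the two
  classes they separate, consulted only when exactly two level-2 machines
  claim the image.

When zero or all three level-2 machines fire, the disease with the largest
signed decision value wins.  This margin fallback uses only values already
computed, so exhaustive enumeration of all outcome combinations confirms a
worst case of five consulted machines.  A decision value of exactly zero
resolves to the negative (second-named) class.

Each machine standardizes features with its own training subset's
mean/scale (RBF kernels are scale-sensitive) and selects (C, σ) by
stratified k-fold grid search maximizing mean accuracy, ties broken toward
smaller C then smaller σ — a deterministic preference for the smoother
model.  The default grids are C, σ ∈ {2⁻², …, 2⁸} (121 candidates); σ is
mapped to scikit-learn's parameterization as γ = 1/(2σ²).  Machine order
in serialization and summaries is (N|~N, B|~B, T|~T, U|~U, B|T, B|U, T|U).

## Evaluation protocol

The pixel-labeled bank images are disjoint from the image-level
evaluation set; the bank is built once and features are extracted once.
Inside stratified k-fold cross-validation (default 10 folds) only the
cascade — including its per-machine standardization and grid search — is
re-trained per fold, so no test-fold information reaches training.
Requesting n folds on n images switches to leave-one-out with plain
(unstratified) folds, since single-image test folds cannot be stratified.

Multiclass metrics are macro-averaged (unweighted over classes), the
conservative choice under the heavy normal-class imbalance typical of
capsule video; classes absent from the truth vector are reported absent
and excluded from the macro means, and undefined binary denominators
(e.g. specificity on an all-diseased set) are reported absent, never 0.
ROC curves sweep the one-vs-rest decision values: the gate's value for N,
each disease machine's value for that disease.

Single-disease reductions (e.g. bleeding-vs-normal) restrict the bank to
that disease's models and train a single level-1-style machine.

## Synthetic image generator

Each image is a circular bright field (radius 0.9 · min(H,W)/2, default
256×256) inside a black border; background pixels draw from a mucosa
color model and lesion pixels from a per-disease model, all trivariate
normals with 8-unit diagonal sd by default:

| population | mean RGB        |
|------------|-----------------|
| mucosa     | (160, 95, 70)   |
| bleeding   | (185, 35, 35)   |
| ulcer      | (215, 205, 165) |
| tumor      | (200, 120, 140) |

Lesions are axis-aligned ellipses (semi-axes 6–20 px, 1–3 per image by
default) placed strictly inside the field, with 1-px Gaussian edge
feathering in the rendered raster only — the ground-truth mask stays the
sharp ellipse.  Generation is bit-deterministic given (config, seed).

Two nuisance processes emulate the frame-to-frame variability of real
capsule video, which a flat iid background would miss entirely:

* a per-image global RGB offset (`illumination_sd`, default 10), the
  exposure/mucosa-tone variation between frames;
* a per-image planar illumination ramp with random direction and
  per-channel amplitude (`gradient_sd`, default 25), the directional-light
  and vignetting component that dominates within-frame intensity variance.

These make global color statistics a nuisance quantity — a whole-image fit
cannot tell a small lesion's contribution from illumination — while local
lesion-vs-mucosa contrast within a frame is preserved.  This is exactly the
regime in which ROI-restricted features are expected to beat whole-image
features, and the benchmark experiments confirm that ordering.

`separable_config()` switches both nuisances off.  In that regime the
class color models are ≥ 60 intensity units apart on at least one channel
with sd 8, a pixel-level Bayes classifier on the generating distributions
exceeds 99% accuracy, and cross-image properties of the color models
themselves (e.g. the same-class vs cross-class ROI Dice asymmetry) hold
for every seed.  With the nuisances on, a discriminant trained under one
illumination can mis-segment under another — realistic behavior, but a
different claim than the color-model asymmetry.

What the generator does **not** emulate: mucosal texture, specular
highlights, folds and debris, lesion-shape irregularity beyond ellipses,
and temporal correlation between frames.  Passing tests therefore
demonstrate the correctness and internal consistency of the pipeline under
controlled conditions, not clinical performance.

## Benchmark problem sizes

The end-to-end experiments (`wcemlda.experiments`) use 3 pixel-labeled
fixtures per disease (bank M = 9), 40 evaluation images per class
(n = 160), single lesions covering ≤ 2% of the field, 10 outer folds,
reduced hyperparameter grids C ∈ {1, 32}, σ ∈ {1, 4, 16} and 3 inner
grid-search folds.  These sizes keep a full run on one CPU in seconds
while leaving every pipeline stage exercised; the library defaults (full
11 × 11 grids, 5 inner folds) remain available through `PipelineConfig`.

## Known limitations

* The discriminants use raw RGB triples only; no spatial regularization
  or morphology is applied to the ROIs.
* Feature vectors grow linearly with the bank size; very large banks make
  the RBF machines expensive and the features redundant.
* The margin fallback for 0- or 3-positive level-2 outcomes is a design
  choice; other tie policies (e.g. consulting all three pairwise machines)
  would exceed the five-machine consultation bound.
* Synthetic results transfer to clinical data only insofar as lesion color
  separability holds there; the generator's palette is a fixture choice.
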
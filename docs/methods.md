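# Methods

## Overview

`stainmap` implements a square-level workflow for identifying prostate
cancer on digitized slide pairs: an H&E section for morphology and a
serially-cut IHC section stained with a triple cocktail (HMWCK + p63 in
brown DAB, AMACR in red Fast Red, hematoxylin counterstain in blue).
Because basal-cell markers disappear in carcinoma while AMACR is
overexpressed, the amount and exclusivity of red versus brown staining
carries most of the diagnostic signal; the H&E compartments (nuclei,
cytoplasm, stroma) supply tissue-composition context.

The unit of analysis is the *analysis square*, a 1,000 × 1,000-pixel grid
cell (0.25 mm² at 0.5 µm/pixel). Each square receives seven features,
a continuous prediction of % malignant epithelium from an elastic net, and
a cancer/benign label for evaluation.

## Colorimetry

**Optical density.** Brightfield transmission follows Beer–Lambert, so
`OD_c = −log10(I_c / I0)` is linear in stain amount per channel
(`I0 = 255` for 8-bit scans). Intensities are clamped at 1 before the log
so ink-black pixels map to a finite OD (≈2.41) instead of infinity.

**Color deconvolution.** The three stain OD signatures — Fast Red
(0.283, 0.949, 0.757), DAB (0.461, 0.826, 1.0), hematoxylin
(0.21, 0.276, 0.176) — are normalized to unit Euclidean length before the
3×3 basis is inverted; concentrations are therefore OD units along each
unit basis direction. The printed (raw) vectors are preserved verbatim in
the default configuration. Negative unmixed concentrations, which arise
for out-of-gamut colors, are clipped to zero (negative stain amounts are
unphysical). A pixel is *positive* for a chromogen when its concentration
exceeds a per-stain threshold, default 0.15 OD (these thresholds are
instrument-configured in practice and have no published value; 0.15 is a
conservative choice well above quantization noise, ~0.002 OD, and well
below the phantom's rendered concentrations, 0.35–0.8 OD). The mean OD
reported by `cd_quantify` is averaged over positive pixels only, so the
product OD × %Pos scales with both stain area and intensity.

**Positive pixel counting.** A pixel is positive when its
hue/saturation/brightness triple (standard HSV; hue in degrees, achromatic
hue = 0) falls in a configured box; the hue interval is modular so ranges
may wrap through 0°/360°. The three compartment boxes of a PPC
configuration must be pairwise disjoint — validated at construction — which
guarantees % nuclei + % cytoplasm + % stroma ≤ 100 and makes
`% unstained = 100 − (sum)` well defined. One PPC configuration is keyed
per H&E staining batch.

**Co-expression.** `%Pos_CE` counts pixels positive for exactly one of
the two chromogens. Double-stained debris (corpora amylacea and similar)
inflates the plain CD red percentage but not the CE percentage, which is
why the feature set carries both.

## Grid, registration, annotation transfer

The IHC-to-H&E misalignment is modeled as rigid (translation + rotation
about the image center). Registration is an exhaustive search: a coarse
rotation sweep (±5° in 0.5° steps) on 4× downsampled luminance with
FFT-based translation matching at each angle, a 0.05°-step refinement at
2× downsampling, and a final sub-pixel translation estimate at full
resolution. On phantoms this recovers a (12 px, −7 px, 1.5°) offset to
within ~0.3 px and well under 0.1°. Constant (featureless) images are
rejected.

Grid squares tile from the origin; partial squares at the right/bottom
edges are dropped rather than padded, so every feature vector summarizes a
full 0.25 mm². Labeling uses full-resolution rasterized annotation masks
with pixel-center sampling (a pixel belongs to a polygon iff its center is
inside), which makes the ≥75 % boundary exact for axis-aligned regions.
A square is cancer when its overlap with the union of cancer regions is
≥0.75; it inherits the Gleason score of the region with the largest
overlap, ties resolved toward the higher grade (the clinically
conservative, deterministic choice — the source procedure does not specify
one). Negative-annotation overlap ≥0.75 excludes a square, taking
precedence over labeling; a > 99 %-unstained square (strict inequality) is
excluded as off-tissue.

## Regression model

The elastic net minimizes

    (1/2m)‖Xω − y‖₂² + αρ‖ω‖₁ + (α(1−ρ)/2)‖ω‖₂²

Features are standardized (zero mean, unit variance, statistics computed
on the training portion only inside each CV fold) and an unpenalized
intercept is carried; `y` stays on the 0–100 scale. Penalizing raw-scale
features would mix percentages with OD-products and make α meaningless.
Optimization is cyclic coordinate descent with soft-thresholding on the
Gram formulation, started at ω = 0, stopping when the largest weight
change in a sweep falls below 1e−8. With exactly collinear columns (the
CE percentages are nearly proportional to the CD percentages by
construction) and α ≈ 0 the minimizer is not unique; a secondary stop on
objective stagnation (relative decrease < 1e−10 per 20 sweeps) returns a
point whose objective is converged even though individual weights may
still drift along the flat direction.

Cross-validation is leave-one-WSI-pair-out: each fold holds out all
squares of one pair, honoring within-slide correlation. Hyperparameters
(α, ρ) are selected on a grid — α ∈ 13 log-spaced points in [1e−4, 10],
ρ ∈ {0.1, 0.3, 0.5, 0.7, 0.9, 1.0}; no grid is prescribed by the source
procedure, so these cover four decades of shrinkage and the lasso/ridge
mixing range — minimizing the mean held-out value of the *penalized
objective itself*, taken literally; a held-out-MSE criterion is available
(`criterion="mse"`) since the literal reading mildly favors small-norm
models. Ties break toward larger α, then larger ρ (the sparser model).
Predictions are reported raw (unclipped) — the ROC score — with clipping
to [0, 100] available for map rendering, since whether clipping was applied
upstream is unspecified.

Four feature sets are trained: H&E (3 PPC features), IHC (4 chromogen
features), full minus CE (5), and full (7).

## Evaluation

ROC curves are built over all distinct score thresholds; AUC is the
trapezoidal area, which equals the pairwise concordance probability with
ties counted ½ (asserted against an exhaustive pair-counting oracle in the
tests). The operating point maximizes the Youden index J = sens + spec − 1,
ties toward higher specificity. Sensitivity/specificity at Youden are
computed on the same test data as the ROC (no refit).

Confidence intervals are percentile bootstrap (1,000 replicates by
default), hierarchical: test-set resampling draws WSI pairs with
replacement keeping each pair's squares together; training-set resampling
additionally resamples squares within each drawn pair, at the pair's
original size (the within-group size convention is not specified by the
source procedure; same-size is the standard choice). Replicates on which a
statistic is undefined (single-class resample) are redrawn and counted.
Two-sided p-values for paired differences invert the bootstrap CI on a
0.001 α-grid, floored at 1/n_boot — CI inversion cannot resolve below
replicate granularity. Per-Gleason sensitivities aggregate into grade
groups with GG ≤ 2 = {3+3, 3+4} and GG ≥ 3 = {4+3, 4+4, 4+5, 5+4}.

## The phantom generator

The phantom stands in for slide pairs that cannot be deposited. It is a
forward model, not a texture synthesizer: every pixel has an exact class
(glass / stroma / lumen / benign epithelium / malignant epithelium), and
both images are rendered from per-class stain concentrations through the
same Beer–Lambert model the colorimetry inverts.

Geometry: gland clusters (4 elliptical glands, semi-axes 0.17–0.23 of a
cell) occupy cells aligned with the analysis-square grid; the outermost
cell ring is clear glass (exercising the off-tissue exclusion). Each gland
is an elliptical annulus — lumen core, inner cytoplasmic band, outer
nuclear band — and benign glands carry a 3-px basal ring rendered with DAB.
Malignant clusters render their epithelium with pure Fast Red (0.8 OD)
unless the gland is drawn AMACR-negative; benign epithelium and stroma are
hematoxylin (0.65 / 0.35 OD). H&E rendering uses hematoxylin + eosin
concentrations chosen so nuclei (dark purple), cytoplasm (saturated pink)
and stroma (pale pink) occupy disjoint HSB boxes; the default PPC
configuration is documented alongside so the ranges match.

Cancer annotations are dilated convex hulls of each malignant cluster's
gland union (buffer radius 0.12 of a cell), emulating a pathologist's
coarse outline. Because clusters are confined to grid-aligned cells, every
square's cancer overlap is either near 1 or near 0 — separability of the
labels is forced by construction, which is what makes "AUC = 1 on
noise-free phantoms" a meaningful pipeline check rather than a model
achievement. Negative-annotation artifacts occupy whole gland-free cells.
Stain variability is additive Gaussian noise in OD space (multiplicative
in intensity), SD 0.02 OD by default, clipped to valid intensities;
noise-free glass renders exactly white. The known rigid offset (default
12 px, −7 px, 1.5°) is applied to the IHC rendering only; all truth
rasters stay in the H&E frame. A `debris_fraction` knob adds
double-stained blobs to motivate the CE features; its default is 0 and no
prevalence realism is claimed. The 8-bit images are accompanied by the
pre-quantization OD rasters (`he_od`, `ihc_od`) so forward-model
inversion can be verified below quantization error (~0.002 OD per
channel, the precision floor of any 8-bit path).

What the phantom does **not** emulate: nuclear chromatin and glandular
architecture, stain gradients within a compartment, scanner artifacts
beyond uniform jitter, deformable (non-rigid) section-to-section
distortion, and the real prevalence of PIN/HGPIN mimics. Passing tests
demonstrate that the pipeline's measurements, model and statistics are
internally correct and invert the generative model exactly; they say
nothing about robustness to real histological variability.

## Problem sizes

The default study runs 10 training pairs (40 squares sampled per pair,
400 rows) and 20 test pairs at 2,400 × 1,600 px with 200-px analysis
squares — the same structure as a full-scale study with every linear
dimension scaled so the whole pipeline (rendering, registration,
extraction, tuning, bootstrap) completes in minutes on one CPU. The 1,000-px
square remains the default of the grid module itself and the basis of the
0.25 mm² geometry check.

## Known limitations

- The phantom's color palette is deliberately clean; PPC ranges tuned to
  it will not transfer to real H&E scans without re-sampling control
  regions (the per-batch configuration mechanism exists for exactly that).
- Registration assumes ≥50 % overlap and rigid motion; it has no local
  deformation model.
- The CLI sequences the study in-process; stage subcommands control which
  artifact groups are written rather than re-reading intermediate
  artifacts from disk.
- With exactly collinear features the reported weights are one element of
  the optimal set; predictions and objective values are unaffected.
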
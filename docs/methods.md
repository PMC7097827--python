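# Methods

## The screening problem

In visual inspection with acetic acid (VIA), 3–5% acetic acid coagulates
cellular protein in abnormal cervical epithelium, producing a dense
aceto-white patch, while normal epithelium remains light pink. This package
quantifies that change from a *pair* of cervicograms (before/after acid) and
classifies each of 12 clock-position sectors — the unit at which excised
tissue is graded by histopathology — as VIA-negative or VIA-positive.
Grades normal and CIN1 are treated as screen-negative; only CIN2+ (the
treat-worthy class) is positive. A patient is called positive when at least
one of their 12 sectors is positive.

## Pipeline and its assumptions

**Specular removal.** A pixel is specular when its brightest channel reaches
60% of the 8-bit range. The per-pixel channel *maximum* is used as the
grayscale for this test: true highlights saturate all channels, and the max
is insensitive to the tissue's red cast. Masked pixels are replaced by the
inverse-square-distance-weighted mean of unmasked pixels within a 5-px
radius (nearest-valid fallback deeper inside), which meets the requirement
of a smooth, natural fill without committing to a specific published
inpainting algorithm.

**ROI from bit-planes.** The red channel is sliced into its 8 bit-planes;
the union of the two most significant planes (red ≥ 64) marks the bright
ectocervix. Planes are numbered 0 (LSB) to 7 (MSB), and "the seventh and
eighth" planes are read as indices 6 and 7. Union is the permissive
combination; the strict AND (red ≥ 192) is available via
`bitplane_roi(..., combine="and")`. The raw mask is speckled, so it is
closed with a 5-px disk, reduced to its largest connected component, and
hole-filled. The pre/post masks are intersected (logical AND) so only
tissue visible in both phases is analysed.

**Registration.** Three manual fiducials per image (cervix centre, two os
endpoints) define a rigid transform: rotate about the centre by the negative
os-line angle, then translate the centre to the canvas centre. No scaling is
applied. The endpoint labelled `os_a` maps to the left, fixing a 180°
ambiguity. Images are resampled bilinearly, masks by nearest neighbour.

**Clock slicing.** Sector *k* is the half-open 30° arc centred on clock
hour *k*, hour 12 pointing up, hours increasing clockwise; every ROI pixel
belongs to exactly one sector (pixel-exact partition). The offset between
image clock and histology clock on real data is an acquisition-protocol
calibration; synthetic data adopts the module's convention by construction.

**Features.** Per sector:

| feature | definition | units | direction in CIN2+ |
|---|---|---|---|
| `d_ave` | mean shift of G/R and B/R ratio-histogram modes, post − pre | bins (width 1/128) | higher |
| `sd_green`, `sd_blue` | population SD of post-acetic G and B | 8-bit intensity | higher |
| `astar_mean` | mean CIE-Lab a* of post-acetic sector (sRGB, D65) | a* units | lower |
| `glcm_correlation` | Haralick correlation of the 4-direction GLCM of S<sub>post</sub> − S<sub>pre</sub>, distance 5, 8 levels | dimensionless, [−1, 1] | higher |

Choices the published protocol leaves open, fixed here: ratio histograms
span [0, 2] in 256 bins (pink tissue sits below G/R = 1; whitened tissue
approaches it; larger ratios are clipped into the top bin); the histogram
mode tie-breaks to the lowest bin; the mode difference is *signed*
(post − pre), consistent with the ratio increasing under whitening; GLCM
quantization uses 8 levels over the difference image's own range (the common
texture-analysis default, keeping small sectors well populated); the four
directional co-occurrence matrices are accumulated non-symmetrically and
summed *before* normalization; only pairs with both pixels inside the
sector mask are counted. Sectors with under 50 valid pixels, under 2 pixels
for an SD, a bounding box smaller than the GLCM distance, or a constant
difference image yield a missing value rather than an imputed zero, and
incomplete rows are dropped from training with a log entry.

**Classification.** Predictors are z-scored ("weighted" means/SDs in the
original description; no sample weights are defined anywhere, so weights
default to uniform with a hook exposed). The holdout is taken at patient
level in the workbench (half the patients, hence half the slices, are never
touched during training), and 10-fold cross-validation runs at slice level
inside the training half, with standardization re-fit on each fold's nine
training subsamples (leak-free; `refit_standardization=False` reproduces the
possible fit-once shortcut). Families: KNN (k = 5, Euclidean; score =
positive-neighbour fraction), SVM (poly kernel, degree 4, C = 3,
gamma = 2.2; scores are a logistic squash of decision values — monotone, so
AUC is unaffected, and decision 0 maps to score 0.5 so a single 0.5
threshold applies to all families), and a Gini decision tree grown
best-first with at most 20 total nodes (internal + leaves; implemented as
max 10 leaves since a binary tree with m leaves has 2m − 1 nodes). Summary
metrics are computed from pooled held-out scores at threshold 0.5; ROC/AUC
by threshold sweep with trapezoidal area, which equals the Mann–Whitney
pair-counting statistic with ties counted half (verified against that
oracle exactly in tests). Grid search maximizes CV accuracy with ties broken
by AUC, then grid order.

**Agreement statistics.** κ = (p₀ − pₑ)/(1 − pₑ) with marginal-product
chance agreement. Significance of κ ≠ 0 uses the large-sample Fleiss
standard error under the null; an exact conditional (hypergeometric,
fixed-margins) test is available for n ≤ 30. Printed reader rates are
converted back to integer confusion counts by nearest-integer rounding,
with a warning when a printed rate is not consistent with any integer count;
readers are pooled by cellwise summation (the pooled matrix reproduces the
published average row exactly, which an arithmetic mean of rates does not
guarantee — both summaries can be computed, pooling is the headline).

## The synthetic world

The generator renders what the features assume, not photorealism: a pink
elliptical ectocervix (RGB ≈ (140, 92, 100)) with a bounded smooth shading
field, on a dark background with a dimmer vaginal-wall annulus (red < 64, so
bit-plane masking is non-trivially exercised); a central os slit drawn as
moderately darkened tissue (0.8× the cervix colour) whose endpoints provide
the registration fiducials; saturated specular disks (8-bit max in all
channels, fresh positions per phase); i.i.d. Gaussian pixel noise
(SD 2 by default); and a random os orientation that registration must undo.
Aceto-whitening in a CIN2+ sector multiplies G and B by
(1 + 0.55·strength) and adds a smooth speckle texture (Gaussian-filtered
noise, σ = 6 px, amplitude 10·strength), which raises the ratio modes and
channel SDs, lowers a*, and gives the saturation-difference image the
spatially coherent texture that drives Haralick correlation upward. CIN1
sectors whiten at 0.3× the CIN2+ strength, providing the confusable class
that the binary labelling screens as negative. Default cohort: 20 patients,
60% with at least one CIN2+ sector (matching the 12-abnormal/8-normal
composition of the published reader study), 2–6 abnormal sectors per
abnormal patient; per-patient seeds derive deterministically from the
master seed. Intensity levels are chosen so that, at default parameters,
only specular disks cross the 60% saturation threshold — tissue (including
whitened tissue) stays below it.

What the generator does **not** emulate: vascular patterns (mosaicism,
punctuation), gradual lesion margins, working-distance and illumination
inhomogeneity, fiducial placement error, or inter-patient anatomical
variation beyond geometry randomization. Consequently a green end-to-end
test establishes that the mechanics (masking, registration, slicing,
feature algebra, CV protocol) are correct and that feature *directions*
match expectation — the default world is linearly separable and all three
classifiers reach perfect cross-validated discrimination on it, which says
nothing about clinical accuracy. Published clinical headline figures (KNN
CV accuracy 78.3%, AUC ≈ 0.805) were obtained on undeposited clinical
images and are not reproducible from synthetic data; they are deliberately
not asserted anywhere.

## Numerical and degenerate-input conventions

- Coordinates are 0-based (row, col) with origin top-left; fiducials are
  (x, y) = (col, row), matching the JSON interchange format.
- Seeded `numpy` Generators everywhere; identical (config, seeds) reruns
  are bit-identical end to end (asserted in tests).
- Population (ddof = 0) standard deviations throughout.
- κ is NaN for degenerate marginals (pₑ = 1); sensitivity/specificity are
  NaN, never zero-filled, when their denominator is empty.
- Empty ROI flags an error on all 12 slices; slices always number 12.
- The annulus render places the ring at 1.05× the ROI radius; segments are
  30° arcs aligned to the slicing convention, predictions red (VIA+) / blue
  (VIA−), truth ticks red/green/blue for CIN2+/CIN1/normal, and a yellow
  outer arc marks prediction-truth matches for CIN2+.

## Known limitations

- The bit-plane ROI is a red-brightness heuristic; adjoining bright
  vaginal wall can survive it (as it does in practice), and the intersection
  step only mitigates, not removes, this.
- Multi-cohort test runs use a 224-px canvas (default 512) purely for
  runtime; feature directions are scale-stable but absolute SD values are
  not comparable across canvas sizes.
- The SVM score calibration is rank-preserving but not a probability;
  only its sign (via the 0.5 threshold) and ranks are ever used.
- The exact κ test conditions on both margins, which is conservative
  relative to the unconditional asymptotic test for small n.
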
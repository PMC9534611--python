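# Methods

`wavemics` implements a radiomics workflow for discriminating two brain-tumor
classes (a primary tumor class, label 1, versus metastases, label 0) from
four co-registered MRI sequences (T1W, T2W, T1C, FLAIR). The pipeline has six
stages; each is a standalone module and a CLI subcommand.

## 1. Synthetic cohorts

Patient MRI cannot be redistributed, so `wavemics.synthetic` generates
cohorts with the study's structure rather than its population statistics:

* **Lesions** are ellipsoids with per-class radius distributions (defaults:
  class 1 semi-axis scale 7–11 mm, class 0 5–9 mm, each axis shrunk by a
  uniform 0.7–1.0 anisotropy factor), centred near the field-of-view middle
  with ±2 mm jitter.
* **Texture** inside the ROI is Gaussian-filtered white noise with a
  class-specific correlation length (2.5–3 mm for class 1, 1–1.2 mm for
  class 0) plus class- and sequence-specific mean/SD, over a white-noise
  background (mean 100, SD 15, arbitrary units). Filtering length and
  variance differences give every gray-level texture family genuine
  class signal; radius distributions give the shape family signal.
* **Repeated segmentations** (2 readers × 2 sessions) perturb the reference
  mask by independent boundary-voxel flips (probability `reader_jitter/2`
  per shell voxel on the inner and outer one-voxel shells) plus a localized
  one-voxel dilation/erosion patch. The perturbation is halved and redrawn
  until Dice with the base mask is ≥ 0.92, which guarantees pairwise Dice
  ≥ 0.8 between any two re-segmentations by construction. The default
  `reader_jitter = 0.15` produces per-feature ICCs straddling the 0.75
  threshold on small cohorts.
* Determinism: the cohort seed is spawned per patient via
  `numpy.random.SeedSequence`, so identical configs give bit-identical
  cohorts regardless of patient count ordering.

What the generator does **not** emulate: MR physics (bias fields, noise
correlations, partial volume), inter-sequence misregistration, multifocal or
non-ellipsoidal lesions, and any calibration to a real patient population.
Passing tests therefore demonstrate that the pipeline machinery is correct
and that it recovers planted structure — not clinical performance on real
data.

The feature-table generator plants `n_informative` columns with a
class-conditional mean difference of `effect_size` (in units of `noise_sd`)
among pure-noise columns; column names carry the sequence/family scheme of
the real extractor so downstream stages are exercised with realistic names.

## 2. Feature extraction (107 per sequence)

Volumes are resampled to 1×1×1 mm (trilinear; nearest-neighbour for masks),
then in-mask intensities are discretized with a fixed **bin width of 64**
anchored at the ROI minimum: `level = floor((v − min)/64) + 1`. Fixed bin
*width* (not a fixed bin count) follows the convention of mainstream
radiomics extractors.

Families and conventions (IBSI-style):

* **Shape (14)** — mesh volume and surface area from marching cubes at
  iso-level 0.5 on the mask; axis lengths (4√λ), elongation √(λ2/λ1) and
  flatness √(λ3/λ1) from a PCA of physical voxel-centre coordinates;
  maximum diameters from convex-hull surface points; sphericity
  (36π V²)^⅓ / A. The mask is Gaussian-smoothed (σ = 0.7 voxels) before
  triangulation so staircase facets do not inflate the surface area — a
  digital 10 mm ball then measures sphericity ≈ 0.98 instead of ≈ 0.91.
  Masks too thin to survive smoothing fall back to the raw surface.
  Single-voxel masks return axis lengths 0 and elongation/flatness 1.
* **First order (18)** — moments, order statistics and energies on the raw
  in-mask intensities; Entropy and Uniformity on the discretized histogram
  (log base 2). Skewness/kurtosis of a constant ROI are defined as 0;
  kurtosis is the raw (non-excess) m4/m2² form.
* **GLCM (24), GLRLM (16)** — 13 unique 3D direction offsets at Chebyshev
  distance 1; one matrix per direction (GLCM symmetrized and normalized),
  statistics averaged over directions; directions without pairs/runs are
  skipped. Degenerate single-level ROIs use sentinels (Correlation → 1,
  MCC → 1, InverseVariance → 0) instead of raising.
* **GLSZM (16)** — zones are 26-connected components of equal level.
* **GLDM (14)** — dependence size = 1 + number of 26-neighbours (in mask)
  with identical level (α = 0).
* **NGTDM (5)** — neighbourhood average over the in-mask 26-neighbourhood;
  voxels with no in-mask neighbour are excluded.

The four sequences concatenate to one 428-column row per patient
(sequence-major order T1W, T2W, T1C, FLAIR).

Every family is verified against an independent brute-force loop
implementation (matrices and statistics) on small random ROIs to 1e−10.

## 3. Reliability filtering

ICC(2,1) — two-way random effects, absolute agreement, single measurement —
from the standard mean-squares decomposition; a zero-variance matrix is
defined as ICC 1 (perfect agreement on a constant). Intra-observer ICC uses
reader 0's two sessions; inter-observer uses both readers' first sessions.
A feature is kept iff **both** ICCs are strictly above the threshold
(default 0.75). The implementation is cross-checked against pingouin's
ICC(A,1) row.

## 4. Normalization and LASSO selection

Z-scores are fitted on training rows only (70 % stratified split by
default); zero-variance columns are dropped with a warning. Selection is one
L1-penalized logistic regression on the full joint table (all sequences at
once), penalty chosen on a 30-point log grid by stratified 10-fold CV
minimizing the binomial deviance (minimum rule, not 1-SE). Features with
nonzero coefficients are returned in column order; the pipeline widens the
penalty (C × 3 steps) if fewer than four survive, since the wavelet layout
needs one value per sequence row. The workflow's two evaluation protocols
(a 70/30 split and repeated 5-fold CV) are composed as: the split governs
normalization + selection, the repeated CV governs the downstream classifier
comparison with fold-internal re-normalization. This composition is a
declared design choice of the package.

## 5. Wavelet profiles (36 criteria × 31 filter banks)

The selected-feature row (canonical sequence-major order, z-scored with the
training-split statistics — the DWT mixes columns, so they must be on
comparable scales) is reshaped to a 4 × ⌈m/4⌉ matrix — one row per MRI sequence — zero-padded on the right when
4 ∤ m. A single-level separable 2D DWT (symmetric boundary extension) yields
cA, cH, cV, cD under each of 31 banks: bior1.3–bior5.5 (11), db2–db9 (8),
sym2–sym8 (7), coif1–coif5 (5). Per bank the profile is:

* 7 criteria × 4 matrices = 28: max, min, mean, median, SD, Shannon entropy,
  energy. Entropy uses the normalized coefficient-energy distribution
  p_i = c_i²/Σc² (coefficients are signed), log base 2, 0·log 0 = 0,
  all-zero matrix → 0.
* 2 × 3 = 6: OLS slope and slope standard error of each detail matrix
  regressed (with intercept) on cA; a zero-variance cA gives (0, 0).
* 2 whole-signal criteria: energy Σx² and waveform length Σ|x_{i+1} − x_i|
  (the summed absolute first difference — the standard signal-processing
  reading of a "wavelength" criterion).

Profiles are fully deterministic. The DWT is verified against a direct
convolve-and-downsample oracle per family, and orthogonal banks are checked
for energy conservation under periodized extension.

## 6. Classifier benchmark

Eight families with fixed documented defaults (sklearn): RBF SVM (C=1,
margin scores), GaussianNB, MLP (one hidden layer of 50, max 500 iters),
decision tree, AdaBoost (100 estimators), 5-NN, logistic regression, random
forest (100 trees). Evaluation is stratified 5-fold CV repeated 100 times
(repeat r seeds the fold shuffle with `seed + r`); each fold re-fits
z-scores on its training part, so no leakage. Metrics: accuracy, AUC, F1
with positive class = label 1. The grid covers 31 banks × 8 classifiers =
248 wavelet cells plus 8 plain cells; the best cell is the arg-max of mean
AUC with ties broken by accuracy, F1, then lexicographic bank id.

Per classifier, the best wavelet bank is compared with the plain model via
the signed percent increase 100·(w − p)/p (one decimal) and DeLong's test
for correlated ROC curves on the first repeat's pooled held-out scores,
two-sided, α = 0.05, uncorrected across classifiers (single-test reading).
The DeLong implementation is checked against a paired permutation oracle
and the Mann–Whitney identity.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately small cohorts (12–20 patients,
12×16×16 voxel volumes, 3.5–5.5 mm tumors) and reduced repeats (1–5); these
sizes are the package's default desk-scale configuration and are stated in
each test. Tolerances: texture/DWT oracle agreement 1e−10; normalized
matrices sum to 1 within 1e−12; chance-level AUC band ±0.05; planted LASSO
recovery ≥ 80 % over 20 seeds; the reduced-scale wavelet-vs-plain
directional check allows 0.02 Monte-Carlo slack.

## Known limitations

* Feature values follow this package's own documented conventions; other
  extractors may differ in binning anchors, aggregation, or mesh handling.
* The 4-row signal layout and the waveform-length criterion are declared
  interpretations of an under-specified construction.
* DeLong p-values are asymptotic; at n ≲ 40 they can differ from exact
  permutation by a few hundredths.
* Synthetic cohorts demonstrate machinery, not clinical performance.
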
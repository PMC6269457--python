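# Methods

This document specifies the model implemented by `mammotex`, the default
parameter values and why they were chosen, the scope of the synthetic data
generator, the numerical conventions, and the known limitations.

## 1. Anatomical parameterization

**Breast silhouette.** Otsu thresholding on `log1p` intensities, followed by
morphological closing (disk radius 2) and largest-connected-component
selection. The log transform makes the air/tissue split dominate the
between-class variance even when the bright pectoralis makes the raw
histogram trimodal.

**Pectoralis boundary.** A straight line fit by a Hough transform restricted
to plausible MLO geometry: angles 20°–80° from vertical in 0.5° steps,
gradient-magnitude votes, minimum support `max(20, 0.25·H)` votes for an
image of height `H`. Absence of a sufficiently supported line is reported as
"no pectoralis" (the rotation falls back to identity, flagged with a
warning), never silently guessed.

**Density clusters.** Weighted one-dimensional fuzzy c-means (`K = 4`
clusters, fuzzifier 2) on parenchymal intensities, initialized at intensity
quantiles for determinism. Cluster labels are sorted so label 1 = fattiest,
label K = densest; "dense tissue" = clusters whose centroid exceeds the
midpoint of the extreme centroids. `K = 4` mirrors the standard BI-RADS-like
four-class density convention and is configurable.

**Standardized frame.** Right breasts are mirrored; the image is rotated
about its center so the pectoral boundary is vertical at the left. All
downstream geometry lives in this frame, making left/right pairs exactly
comparable (signatures are mirror-invariant to within interpolation error;
see §6).

**Landmarks and quadrants.** The nipple is the centroid of breast pixels
inside a 1.5 cm box anchored at the rightmost breast column — a deliberately
simple, deterministic estimator adequate for the nipple's role as a polar
origin. `r_P` is the perpendicular distance from the pectoral line to the
nipple. The central breast area (CBA) is breast tissue within `f·r_P` of the
nipple; the upper-outer area (UOA) is breast tissue above the nipple row and
beyond `f·r_P`. `f` is restricted to `[0.5, 1]` so the two quadrants are
non-degenerate; the default `f = 0.6` leaves both quadrants well populated
on typical MLO geometry.

## 2. Polar texture sampling

A nipple-centered polar grid partitions the parenchyma: rings of radial
width `D` (default `D = 6.3 mm`, matching the classic 6.3 mm lattice
window used in mammographic texture analysis);
`N_s = max(8, round(π·r_P / D))` equal-angle sectors, so sector arc length
at radius `r_P` is about `D` and regions are roughly isotropic. Regions are
retained if they cover ≥ 50 % of their nominal area and ≥ 25 pixels —
discarding slivers whose texture statistics would be dominated by estimation
noise. Each region's azimuth is the angular center of its sector.

## 3. The 34 texture descriptors

Per region, on intensities quantized to `G = 128` levels over the
*whole-breast* range (so levels are comparable across regions):

- **TF1–TF13, histogram:** 5th/95th percentiles and tail means, entropy,
  kurtosis, max, mean, min, standard deviation, skewness, sum, median.
- **TF14–TF20, GLCM:** contrast, correlation, homogeneity, energy, entropy,
  inverse difference moment, cluster shade from a symmetric, normalized
  co-occurrence matrix.
- **TF21–TF31, run length:** the 11 Galloway statistics (SRE, LRE, GLN,
  RLN, RP, LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE) from maximal
  constant-level runs.
- **TF32–TF34, structural:** Sobel edge index (mean gradient over mean
  intensity), box-counting fractal dimension of the supra-median pattern,
  and the fraction of non-uniform local binary patterns (8 neighbors,
  radius 1).

**Anatomy alignment.** GLCM offsets and run directions are the local radial
(toward the nipple) and tangential unit vectors at the region's azimuth,
rounded to the nearest of the four pixel directions
`(0,1), (1,0), (1,1), (1,−1)`. Rounding to pixel directions keeps the
co-occurrence geometry exact (no interpolation of levels) at the cost of a
≤ 22.5° orientation discretization.

**Degenerate-region conventions** (fixed, documented, and tested): a
constant region has GLCM contrast 0, energy 1, entropy 0, and correlation,
skewness, kurtosis 0; a region whose bounding box is smaller than 8×8 has
fractal dimension 0 (flagged). These conventions keep signatures finite
without ad-hoc NaN handling.

## 4. Anatomical weighting and the signature

Per region `i` with centroid `x_i`:

- `S_i = a·(1 − d̂_CBA(x_i)) + (1 − a)·(1 − d̂_UOA(x_i))`, where `d̂` are
  distances to the CBA/UOA pixel centroids, max-normalized over regions.
- `T_i = b·ĉ_i + (1 − b)·(1 − ĉ_i)`, where `ĉ_i = (mean cluster label − 1)/(K − 1)`
  is the region's dense-tissue composition in `[0, 1]`.
- `W_i = c·S_i + (1 − c)·T_i`, computed literally as written, so the
  identity holds to the last bit and `S, T, W ∈ [0, 1]` by construction.

Defaults `a = 0.8, b = 1, c = 0.4` emphasize the CBA within the position
term, score dense tissue only in the tissue term, and mix
40 % position / 60 % tissue — the configuration this package treats as its
reference operating point (and the center of the `optimize_parameters`
search space). The
per-breast signature is the per-feature mean and population standard
deviation of the weighted region features: 34 + 34 = 68 elements.

## 5. Modeling and statistics

- **Design matrix:** per-woman bilateral-average signatures; features with
  pairwise |Pearson r| > 0.90 are pruned (the member with the smaller IQR is
  dropped) before model fitting, and z-scored inside each training fold
  (never on the full cohort) to avoid leakage.
- **Model:** elastic-net logistic regression (saga solver), hyperparameters
  `(l1_ratio, C)` chosen by nested stratified cross-validation on pooled
  inner out-of-fold AUC; ties break toward the strongest penalty. The
  statsmodels-style API (`TextureRiskModel(...).fit() → TextureRiskResults`
  with `.summary()`) exposes fold assignments, per-fold hyperparameters,
  out-of-fold predictions, and the final refit coefficients.
- **AUC:** the Mann–Whitney rank statistic (midranks for ties); bootstrap
  (stratified, 2000 draws by default) for the confidence interval.
- **DeLong test:** fast midrank implementation of the paired-AUC z-test;
  when the variance of the difference is numerically zero the p-value is 1
  for a zero difference and 0 otherwise.
- **NRI:** category-free (continuous) net reclassification improvement,
  case and control components reported separately.
- **Grid search:** `optimize_parameters` rebuilds signatures from cached
  per-region features for each `(D, f, a, b, c)` tuple, so segmentation and
  texture extraction run once per `D`. Because a single CV partition's AUC
  is a noisy selection statistic, the selection metric is averaged over
  `n_repeats` independent outer-fold partitions (seeds `seed + 101·r`).
- **Lattice baseline:** a square lattice (6.3 mm spacing and window by
  default) over the same parenchyma mask, feeding the *identical* texture
  code path, so anatomy-versus-lattice comparisons isolate the sampling
  geometry and weighting.

## 6. Synthetic phantom generator — scope

The generator produces *structurally* MLO-like images for pipeline
validation, not realistic mammograms: a half-elliptical breast with a nipple
bump on a left chest wall, a 30° pectoral wedge bounded by a straight line,
smooth dense-tissue blobs, and Gaussian-random-field parenchymal noise, at
128 × 104 pixels and 0.7 mm spacing. Ground truth (masks, nipple point,
pectoral line, effect locus) is emitted exactly.

Design choices that matter for validation:

- **Dense-blob placement** spreads blobs over the whole parenchyma
  (radial fraction ~ Beta(1.6, 1.6) along the nipple-to-chest axis, angles
  up to ±75° around it), so dense tissue occurs in both the CBA and the
  UOA and the position/tissue weight parameters are not trivially
  confounded. Blobs cover roughly 5 % of the parenchyma, leaving most dense
  tissue concentrated rather than diffuse.
- **Case effects** multiply the noise standard deviation by
  `sqrt(1 + effect_size)` inside an anatomically defined locus
  (e.g. `cba_dense` = dense tissue within the CBA), i.e. the planted signal
  is a *texture variance* change in specific anatomy, which is exactly what
  the weighted signature claims to detect.
- **Cohorts** give each woman her own geometry and texture (breast size,
  pectoral angle ±8°, blob count/contrast, noise scale and correlation
  length jittered per woman), bilateral images with the right side an exact
  mirror of an independent draw, and covariates (age, BMI, density) for the
  baseline-augmentation workflow.

## 7. Numerical conventions

- Feature tables are written with `%.17g` and read back with pandas'
  `float_precision="round_trip"`, so a write/read cycle is bit-exact.
- The saga elastic-net estimator is constructed with an explicit
  `random_state`; the whole pipeline is deterministic given `(config, seed)`
  and the CLI's JSON/TSV outputs are byte-identical across reruns.
- Quantization maps the whole-breast intensity range uniformly onto levels
  `1..G`; a constant range maps everything to level 1.
- The polar grid, GLCM accumulation, and run-length extraction are
  vectorized over the region label map (lexsort/bincount on traversal
  orders), with small-region brute-force reference implementations kept in
  the package and tested to 1e-10 agreement.

## 8. Limitations

- **Weak identifiability of `a` at desk scale.** The position term enters
  the signature near-collinearly: on the default phantom the per-region
  weight vectors for `a = 0.2` and `a = 0.8` correlate at 0.66, and after
  mixing with the shared tissue term at `c = 0.4` the resulting weight maps
  are close to affine transforms of each other. Mean/std-summarized
  signatures for different `a` values therefore nearly coincide, and
  cross-validated AUC separates them only weakly: in repeated synthetic
  parameter-recovery experiments (planted CBA-dense effect, n = 125,
  10 cohort seeds) the grid search recovered the tissue parameter `b`
  in 10/10 replicates but the joint `(a, b)` optimum in only 6/10, with the
  anatomy-weighted model beating the lattice baseline in 9/10. Recovering
  `a` reliably needs either larger cohorts or a signature that retains
  region-resolved (not just mean/std) information.
- **Null calibration is unbiased but noisy.** Over 20 null cohorts
  (n = 125, 25 cases), cross-validated AUCs ranged 0.43–0.74 with mean
  0.53 — consistent with the theoretical null AUC standard deviation
  `sqrt((m+n+1)/(12mn)) ≈ 0.07` plus CV over-dispersion. Single-cohort null
  AUCs far from 0.5 are expected at this size and are not evidence of
  leakage.
- The phantom is not a substitute for clinical validation: no scanner
  physics, no compression deformation, no skin line/artifacts, and case
  effects are idealized variance changes.
- The nipple estimator assumes the nipple is the anterior-most breast
  structure in the standardized frame; on atypical geometries (e.g.
  extreme ptosis analogues) it degrades gracefully but is not robustified.
- The pectoral boundary is modeled as a straight line, the standard MLO
  approximation; curved boundaries bias `r_P` slightly.
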
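# Methods

This note records the modeling assumptions, parameter defaults, and
numerical conventions behind `habikit`, and what the synthetic validation
does and does not establish.

## Imaging model and grids

Volumes are 3D scalar arrays in HU with spacing, origin and direction
matrix; arrays are indexed (z, y, x). Masks are binary, grid-aligned with
their image; a grid mismatch is a hard error, never a silent resample,
because segmentations are meaningful only on the grid they were drawn on.
Analysis runs on a 1 mm isotropic grid (the field's convention for
multi-scanner harmonization): images are resampled trilinearly, masks by
nearest neighbour. Resampling preserves smooth-shape mask volume to within
about 5% (asserted on a digital sphere); B-spline interpolation is available
behind a flag. Voxel-count volume is `N_v × V_voxel`.

## Habitat partition

Each tumor voxel contributes (intensity, local entropy). Entropy is the
base-2 Shannon entropy of the gray-level histogram over the voxel's cubic
neighbourhood intersected with the mask, with bins fixed per patient over
the masked HU range and ε = 1e-12 added inside the logarithm as a p = 0
guard (the placement is configurable).

Defaults and why:

* **Neighbourhood radius 1** (27 voxels). Larger windows straddle habitat
  boundaries in centimetre-scale tumors; empirically, radius-2 windows
  contaminate enough voxels with mixed histograms that cluster-number
  selection over-segments, while radius 1 keeps the entropy estimate local
  and recovers planted habitat counts reliably. Radius 2 and a per-slice 2D
  mode remain available (`window`, `per_slice`).
* **32 entropy bins** over the per-patient masked HU range.
* **Pooled, population-level clustering.** Voxels from all *training*
  patients are pooled and z-standardized with pooled statistics (HU and
  bits are incommensurate scales; unstandardized Euclidean distance would
  be dominated by HU). Validation patients are standardized with the
  frozen training parameters and assigned to the nearest frozen centroid —
  no validation information reaches the fit. A per-patient clustering mode
  is deliberately not offered; the population-level fit is what makes
  habitat ids comparable across patients.
* **k-means** is Lloyd's algorithm with k-means++ initialization, best of
  10 restarts (scikit-learn); determinism under a fixed seed is part of the
  contract. The CH index is computed by this package (trace-of-scatter
  form) and cross-checked against both a brute-force oracle and
  scikit-learn in tests; zero within-cluster dispersion returns an `inf`
  sentinel. k is the CH argmax over k ∈ [2, 6] by default, ties toward
  smaller k.
* **Canonical habitat ids**: clusters are renumbered by ascending centroid
  intensity, so "Sub1" is the lowest-attenuation habitat in every run and
  the labeling is invariant to k-means label permutation.

## Texture features

Every feature is implemented in this package and validated against
brute-force enumeration on small instances; the conservation laws
(Σ length·R = Σ size·Z = Σ D = voxel count) are fuzz-tested on random
volumes.

* **Discretization**: fixed bin width 25 HU for the `original` image
  (levels anchored at the region minimum); fixed bin count 32 for filtered
  images, whose intensity scale is arbitrary.
* **LoG** at σ ∈ {1..5} mm: per-axis Gaussian second derivatives,
  spacing-aware, summed — the response is in 1/mm² units. Kernels are
  truncated at 8σ so a constant image maps to numerically zero (scipy's
  default 4σ truncation leaves a visible DC leak). σ below half the voxel
  spacing warns.
* **Wavelets**: one-level separable stationary (undecimated) transform,
  coif1, symmetric padding; subband letters follow (z, y, x) axis order and
  the centering convention of `np.convolve "same"`. A decimated orthonormal
  mode (via PyWavelets) exists for energy-conservation checks.
* **Matrix families**: GLCM over the 13 unique distance-1 offsets,
  symmetric, features averaged over offsets (aggregation by matrix merging
  is deliberately not the default); GLRLM over the 13 directions; GLSZM
  zones and GLDM dependences use 26-connectivity; NGTDM over the
  26-neighbourhood. Degenerate-region conventions keep tables rectangular:
  single-gray-level regions return Correlation = 1 and inverse-difference
  features = 1; constant regions return variance 0 and NaN
  skewness/kurtosis; GLDM small-dependence emphases sum over dependence ≥ 1
  (an isolated voxel has no neighbourhood to weight). Percentiles use
  numpy's linear interpolation; kurtosis is non-excess (normal → 3).
* **Shape** (mask-only, computed once per region): voxel-count and
  marching-cubes mesh volume, mesh surface area, sphericity
  `(36πV²)^⅓ / A`, maximum 3D and in-plane diameters via convex hulls, and
  PCA axis lengths (4√λ) with elongation/flatness.

**The 1218-feature manifest.** The per-region panel is a versioned JSON
declaring 14 shape features + 14 filter images × 86 features (first-order
18, GLCM 21, GLRLM 16, GLSZM 16, GLDM 10, NGTDM 5) = 1218 exactly. The
decomposition is this package's declared convention: GLCM omits the
information-measure trio (Imc1/Imc2/MCC) and GLDM keeps a 10-feature
subset, choices made so the panel totals the reference count while covering
every feature named in the shipped radscore fixtures. A `small` manifest
(original filter only, 69 features) serves cohort-scale experiments where
the filter bank's cost is not the point.

## Feature selection and radscore

Stages are strictly nested: ICC → correlation → mRMR → LASSO.

* **ICC**: two-way mixed-effects, absolute-agreement, single-measure
  (ICC(A,1)), vectorized from the ANOVA mean squares and cross-checked
  against pingouin; pass threshold 0.70; undefined (zero-variance) ICCs
  fail.
* **Correlation filter**: greedy elimination at |Pearson r| > 0.75,
  visiting features by outcome relevance (variance when no outcome), ties
  lexicographic; the survivors are certified pairwise-compliant post hoc in
  tests.
* **mRMR**: MID scheme — add argmax I(f; y) − mean I(f; s) — with mutual
  information on quartile-discretized features; default shortlist m = 50.
  mRMR precedes LASSO (standard radiomics practice; the final sparse fit is
  the last stage).
* **LASSO**: L1-penalized logistic path (saga, unpenalized intercept,
  warm-started down a 40-point geometric λ grid from λ_max), penalty chosen
  by mean held-out deviance over stratified folds — 10-fold by default with
  a config switch (5-fold is the common alternative); fold counts cap at
  the minority-class size so every fold holds both classes. Features are
  standardized internally; reported coefficients are transformed back to
  the raw feature scale, and the penalized coefficients are used directly
  (no refit), matching how published radscore formulas are written. When a
  fit shrinks every coefficient to zero the intercept is set to its closed
  form logit(ȳ) rather than the solver's partially converged value.
* The published models ship verbatim as fixtures. The subregional formula
  as printed chains some terms with "×" where a linear score requires "+";
  it is interpreted as a linear combination of 7 terms (products would be
  inconsistent with LASSO output); the intercept-at-zero check is
  interpretation-invariant. The two fixtures enumerate 6 + 7 = 13 features
  while the source text reports 12 selected features; the discrepancy is in
  the source and is preserved, not reconciled.

## Statistics

AUC is the Mann-Whitney probability with half tie credit; the same number
is recomputed from DeLong structural components (midranks), and the two
must agree exactly — a permanent internal cross-check. Confidence intervals
use the DeLong variance; operating points maximize Youden's J with ties to
higher specificity; paired model comparison is DeLong's test (identical
ranks → Z = 0, p = 1). AUCs are compared by DeLong and AICs reported
side-by-side (a "test" on AIC is not defined). Cohort tables use
Mann-Whitney U for continuous variables and uncorrected χ² for categorical
ones, switching to Fisher's exact test for 2×2 tables with any expected
count below 5. Splits are stratified 7:3 by outcome, seeded. Two-sided
p-values throughout; no multiple-testing correction. Calibration curves bin
predictions into 10 equal-width bins; decision curves use
`NB(pt) = TP/n − (FP/n)·pt/(1−pt)`.

## The phantom generator

Each phantom is an ellipsoid (semi-axes drawn from 8–14 mm by default) on a
1 mm grid, partitioned into k contiguous habitats — Voronoi cells of random
interior seeds by default, concentric equal-volume shells behind a flag
(both patchy and ring-like patterns occur in real tumors). Habitat texture
is a Gaussian random field: white noise smoothed at the habitat's
correlation length and rescaled to its nominal SD. Default habitats:

| habitat | mean (HU) | SD (HU) | corr. length (mm) | phenotype sketch |
|---|---|---|---|---|
| 1 | 20 | 12 | 0.05 | necrotic-like, noisy |
| 2 | 60 | 10 | 1.0 | intermediate |
| 3 | 105 | 5 | 3.0 | enhancing, smooth |

The means are pairwise separated by at least twice the largest SD (a
generator guarantee, asserted at construction), and the texture scales are
chosen so each habitat occupies a tight niche in (intensity, entropy) space
— near-white high-amplitude noise yields high, stable local entropy; a
smooth low-amplitude field yields low, stable entropy. This is what makes
the planted structure genuinely recoverable by the clustering the method
prescribes; the local entropy of smooth large-amplitude fields is
intrinsically high-variance and would blur the niches. Per-patient jitter
(±2 HU on means, ±15% on SDs) keeps patients distinct.

The binary outcome is Bernoulli from a logistic link on the true habitat
volume fractions plus one subregional texture summary (the realized voxel
SD inside habitat 1), with default coefficients (4, 0, −4, 2). The
texture-summary term carries most of the signal by design: whole-tumor
intensity statistics recover habitat *fractions* rather well (the tumor
mean is nearly the fraction-weighted habitat means), so a fraction-only
link would hand the whole-tumor model almost the same information as the
habitat model. Within-habitat texture is what whole-tumor features dilute,
and is therefore the mechanism that gives the habitat model its true
advantage. The intercept is solved by root-finding so the cohort-mean
outcome probability equals the prevalence target (0.35 by default — a
moderately enriched high-risk cohort). Clinical covariates are simulated
with realistic marginals (age ≈ 66 ± 9, ~48% EGFR, marker medians near
reference ranges) but are independent of the outcome, making the clinical
model an honest null baseline. One global seed spawns independent
per-patient substreams, so cohorts are bit-reproducible, also under
parallel generation.

What the phantoms do **not** emulate: scanner physics and reconstruction,
contrast kinetics, atelectasis or vessel exclusion, irregular (non-ellipsoidal)
tumor boundaries, spatially correlated inter-reader disagreement, and any
dependence of clinical covariates on the outcome. Passing tests therefore
establish the *machinery* (recovery of planted structure, calibration of
tests, correctness of formulas), not clinical performance on real CT.

## Experiment scales

The repeated-seed studies run at sizes chosen to make their Monte-Carlo
error small relative to the effect under test while staying desk-scale:
habitat-count recovery uses 20 cohorts of 20 phantoms; DeLong type-I
calibration uses 2000 null replicates at n = 100; selection recovery uses
10 seeds of 200 candidates at n = 200; the three-model AUC contrast uses 10
cohorts of 120 patients with compact tumors (6–10 mm semi-axes) and the
`small` manifest — the contrast is about model ordering, not the filter
bank, and the ordering is stable at this scale.

## Known limitations

* Feature values follow this package's documented conventions; exact
  numeric parity with any specific third-party extractor version is a
  non-goal (aggregation, binning and boundary conventions differ across
  extractors).
* The entropy feature uses equal-width bins over the patient's masked HU
  range, so a single extreme voxel rescales a patient's bins.
* GLCM information-measure features (Imc1/Imc2/MCC) are not in the default
  panel.
* The LASSO path optimizer is stochastic-gradient based; coefficients are
  reproducible under the fixed internal seed but may differ from coordinate-
  descent implementations in the last digits.
* `ingest_external` validates grids and ids but applies no intensity
  harmonization; multi-scanner batch effects are out of scope.
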
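# Methods

## Segmentation

The ROI of a lesion is defined from a seed voxel and a search radius (default
15 mm): the SUV maximum `M` is located within the radius (physical distance
between voxel centers), and the ROI is the 26-connected component of
`{SUV >= 0.4 M}` that contains the voxel achieving `M`. The threshold
comparison is inclusive (`>=`); the choice only matters on measure-zero ties
but is fixed and documented. 26-connectivity is the conventional choice for
3D hot-spot growing. The seed replaces interactive VOI placement: any seed
whose search ball covers the hot spot yields the same ROI, and re-seeding
from inside the returned ROI is idempotent (tested). Raising the threshold
fraction can only shrink the ROI (tested). No partial-volume correction is
applied.

## Quantization

Gray-level resampling is absolute: 64 bins of width 0.3125 SUV over
[0, 20], `level = 1 + floor((SUV - 0) / 0.3125)` clipped to [1, 64]. Bins
are left-closed/right-open with the last bin closed via clipping, so SUV
0.3125 falls in level 2 and anything at or above 20 in level 64. Values
above the upper bound are therefore indistinguishable past level 64 — a
property of absolute resampling, not a defect.

## Feature bank

Conventional features use raw SUV; histogram and matrix features use the
quantized levels. All moments are population moments (divisor N).

* SUVpeak is the mean over *grid* voxels whose centers lie within a sphere
  of 0.5 or 1 mL centered on the SUVmax voxel; the sphere is not relocated
  to maximize the mean. If the sphere leaves the grid, the mean is taken
  over in-grid voxels and a warning is emitted.
* MTV is the ROI volume in mL; TLG = SUVmean x MTV.
* Histogram skewness/kurtosis are the third/fourth standardized voxel-wise
  moments of the level distribution (kurtosis non-excess, normal ~ 3); both
  NaN for a zero-variance ROI. Entropy uses log2 over occupied bins.
* Shape: the surface is the marching-cubes isosurface at 0.5 of the mask
  after a fixed 1-voxel Gaussian anti-aliasing filter. The raw staircase
  surface of a binary mask overestimates a smooth boundary's area by
  10–14% at any resolution and does not converge; the filtered isosurface
  reproduces a sphere's area to under 1.5% at radius 10 voxels. For very
  thin or porous masks that the filter would erase entirely (maximum below
  the iso-level) the raw binary surface is used instead. Enclosed volume is
  the signed-tetrahedron sum over the oriented mesh, so internal cavities
  of porous thresholded ROIs are subtracted consistently. Compacity is the
  printed form A^{3/2}/V (dimensionless, 6 sqrt(pi) ~ 10.63 for a sphere),
  not its reciprocal.
* GLCM: 13 directions = the unique half-space of the 26 neighbor offsets,
  distance 1 voxel; each directional matrix counts every in-ROI pair in
  both orders (symmetric) and is normalized to sum 1. Scalars: homogeneity
  `sum C/(1+|i-j|)`, energy `sum C^2`, contrast `sum (i-j)^2 C`, entropy
  `-sum C log2 C`, dissimilarity `sum |i-j| C`, and correlation
  `sum (i-mu_i)(j-mu_j) C / (sigma_i sigma_j)`. Features are averaged per
  direction (not pooled); directions without valid pairs are skipped, and
  correlation averages only directions with positive marginal variance
  (NaN for a constant ROI).
* NGLDM follows the classic neighborhood gray-tone difference conventions:
  per-level totals `s_g` of |level - mean of in-ROI 26-neighbors|,
  coarseness `1 / sum p_g s_g` capped at 1e6 (the cap is returned for a
  perfectly homogeneous ROI), contrast as the intensity-pair term times the
  normalized total difference. Only voxels with at least one in-ROI
  neighbor are counted.
* GLRLM: maximal collinear same-level runs per direction, restricted to
  ROI voxels (runs break at the ROI boundary); the 11 standard
  emphasis/non-uniformity/percentage statistics, averaged over the 13
  directions. GLZLM applies the same 11 functional forms to the sizes of
  26-connected same-level zones (one 3D matrix, no direction average).
* The 64-voxel gate: shape and all matrix families return NaN when the ROI
  has fewer than 64 voxels, mirroring extraction tools that refuse texture
  on tiny volumes; NaN (not omission) keeps cohort tables rectangular.

All four matrix families are verified against brute-force enumeration
oracles (explicit pair walking, run following, BFS flood fill, direct
neighborhood loops) to 1e-10 relative on random small ROIs.

## Screening

ANOVA is the classical one-way F test (degenerate inputs: all groups equal
and constant gives F=0, p=1). AUC uses the rank/Mann–Whitney formulation
with ties counted 1/2; when the raw AUC is below 0.5 the feature sign is
flipped so "positive" always points toward malignancy. The 95% CI is a
stratified bootstrap (2000 resamples by default, seeded) — the CI method is
a package choice, distribution-free and reproducible; exact CI reproduction
against other estimators is not claimed. Pre-selection keeps oriented
AUC >= 0.55 (boundary inclusive). The correlation audit reports pairwise
Pearson r on pairwise-complete rows with a two-sided t-test flag at 0.01;
correlated features are reported, never removed.

Dichotomization evaluates every midpoint between consecutive sorted
distinct values (any threshold between the same order statistics yields the
same table; midpoints are canonical), calling a case positive when its
oriented value is at or above the threshold, and returns the threshold
minimizing the two-sided Fisher exact p. Ties on p (compared at 12
significant digits, so mathematically equal tables tie despite float noise)
are broken toward maximal Youden's J, then the smaller threshold — fully
deterministic. The final set keeps Fisher p < 0.08. Predictive scores are
kept at full precision internally and rounded to integer percent only at
the reporting layer; the averaged PPV/NPV are means of the rounded per-row
values, matching how such tables are usually summarized.

No multiple-testing correction is applied, matching the screening protocol
being reproduced; the threshold-optimized Fisher p is optimistic under the
null (demonstrated by a permutation experiment in the test suite), which is
why this workflow is a screen, not a validated classifier.

## Synthetic phantoms

A phantom is an ellipsoidal nodule (membership by voxel-center inclusion,
spacing-aware) on a gaussian background truncated at 0 SUV (SUV is
non-negative). Nodule intensities are i.i.d. draws from a constant,
gaussian, or lognormal model parameterized by mean and sd in SUV; the
lognormal log-scale parameters are solved from these, and its analytic
skewness `(e^{s^2}+2) sqrt(e^{s^2}-1)` is stored in the ground-truth record
together with the exact ellipsoid volume. No spatial noise autocorrelation
is simulated by default; an optional Gaussian PSF (FWHM in mm) exists but
is off, because texture matrices are sensitive to smoothing and it must be
an explicit choice.

Default cohort (the study-emulating condition): 50 subjects, 32 benign /
18 malignant, on 24^3 grids of 4 mm isotropic voxels, background
1.0 +/- 0.2 SUV. Benign nodules are gaussian with mean uptake U(4, 8) SUV
and CV 0.25; malignant nodules are lognormal with mean U(7, 13) SUV and
CV 0.30 (log-sigma ~ 0.29, analytic skewness ~ 0.93), so malignant uptake
is both hotter and right-skewed. Each subject is independently flagged
"small" with probability 0.44, drawing radii from 4.5–8 mm (raster < 64
voxels even before thresholding) instead of 11–17 mm; regular radii are
sized so the 40%-SUVmax ROI stays above 64 voxels even after the threshold
trims low-uptake voxels — the trim is substantial for heavy-tailed models,
because the sample maximum (hence the threshold) grows with the tail. The
malignant CV of 0.30 balances a clearly right-skewed distribution against
that shrinkage. Cytology categories are simulated by a fixed stochastic map
from the true class (benign mostly TIR2, malignant mostly TIR4/TIR5) solely
so the ANOVA-by-category stage has five levels to consume.

The effect cohort (recovery experiments) turns the same dials to strong,
non-overlapping class separation — benign gaussian U(4, 6) SUV, radii
11–13 mm; malignant lognormal U(9, 13) SUV, radii 15–18 mm; no small
nodules — giving ground-truth AUC ~ 1 (>= 0.85 by design) for skewness,
SUVmax and MTV. Recovery is measured as the fraction of 100 seeded
cohorts in which each injected feature survives both screening gates.

What the phantoms do not emulate: spatial texture (voxel noise is i.i.d.,
so matrix features mostly reflect noise granularity rather than
biological heterogeneity), scanner physics (attenuation, reconstruction,
partial volume), respiratory motion, and any quantitative uptake model of
real benign vs malignant nodules — the class effect sizes are dials, not
population estimates. Passing tests therefore demonstrate correctness of
the measurement and screening machinery, not clinical performance.

## Problem sizes and numerical choices

Tests and the acceptance script use 24^3–34^3 grids, cohorts of 50, 100
seeded recovery runs with 200 bootstrap resamples (the CI is not used by
the selection logic), and brute-force oracle checks on <= 5^3 ROIs; these
sizes make every stochastic check cheap to rerun while keeping the binomial
and bootstrap behavior visible. Degenerate inputs are handled explicitly
throughout: empty masks and single-class labels raise; zero-variance
features give NaN skewness/kurtosis/correlation; zero Fisher margins give
p = 1; zero denominators give NaN predictive values.

## Known limitations

* Exact numeric identity with the original extraction software is not
  guaranteed for the families whose formulas it does not publish (GLCM
  scalar variants, NGLDM, the 22 run/zone features); the conventions above
  are the standard published ones and are frozen by oracle tests.
* The screening stage reproduces a univariate, uncorrected protocol; it is
  deliberately not a validated multivariable model.
* Cohort-dependent quantities of any real patient population (per-feature
  AUCs, thresholds, correlations) are not reproducible from synthetic
  phantoms and are not claimed.
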
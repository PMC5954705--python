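# thyrotex

Texture analysis of [18F]FDG-PET thyroid incidentalomas, rebuilt as a tested,
reusable Python pipeline and exercised end-to-end on synthetic phantom
cohorts.

A thyroid incidentaloma is a focal FDG uptake found on a PET/CT performed for
an unrelated indication. Only a minority of such nodules are malignant, and
SUVmax alone separates the classes poorly, so radiomic descriptors of the
uptake distribution and texture are screened as candidate predictors of the
final (benign vs malignant) diagnosis. The package is aimed at researchers
who want the whole chain — segmentation, quantization, feature bank,
univariate screening — as importable, testable code rather than workstation
software.

## What it computes

**Segmentation.** A lesion ROI is the 26-connected component of
`{SUV >= 0.4 * SUVmax}` containing the hottest voxel near a seed point.

**Quantization.** ROI intensities are resampled onto 64 gray levels in
absolute terms over [0, 20] SUV: `level = 1 + floor(SUV / 0.3125)`, clipped
to [1, 64].

**Feature bank.** Per lesion: conventional metrics (SUVmin/max/mean/std,
SUVpeak in 0.5 and 1 mL spheres, MTV, TLG = SUVmean x MTV); histogram moments
on the quantized levels (skewness, non-excess kurtosis, entropy, energy);
shape (sphericity, compacity = A^{3/2}/V from a triangulated surface); and
the four 3D texture-matrix families — GLCM (13 directions, distance 1,
symmetric, direction-averaged), NGLDM (26-neighborhood gray-level
differences), GLRLM (run lengths, 13 directions) and GLZLM (26-connected
zone sizes). Shape and matrix features are NaN for ROIs under 64 voxels.

**Screening.** Per feature: one-way ANOVA against cytology category and
against diagnosis; ROC AUC (rank formulation, stratified-bootstrap CI) with
pre-selection at AUC >= 0.55; a Pearson mutual-correlation audit (flagged at
the 0.01 level, nothing removed); dichotomization at the threshold
minimizing the two-sided Fisher exact p with a final gate at p < 0.08; and
sensitivity/specificity/PPV/NPV from the truth table at the optimal cutoff.

**Phantoms.** Since no patient images are distributed, a generator renders
ellipsoidal nodules (gaussian or lognormal voxel intensities on a noisy
background) with known analytic moments and volumes, and assembles cohorts
of 50 subjects (32 benign / 18 malignant) in which ~44% of nodules are sized
below the 64-voxel gate.

## Worked example

```python
from thyrotex import (IntensityModel, PhantomSpec, make_phantom,
                      segment_nodule, extract_all)

grid, _, rec = make_phantom(PhantomSpec(
    nodule_radii_mm=(14.0, 13.0, 13.5),
    intensity=IntensityModel("lognormal", mean=9.0, sd=2.7),
    rng_seed=11,
))
roi = segment_nodule(grid, rec["center_voxel"])
f = extract_all(grid, roi)
print(f["mtv_ml"], f["hist_skewness"], f["shape_sphericity"])
```

prints (see `examples/03_extract_features.py` for the full narrative):

```
ROI: 118 voxels, MTV 7.55 mL, TLG 75.7
SUVmax 17.94, SUVpeak(0.5 mL) 8.43
histogram skewness 1.28 (right-skewed uptake distribution)
sphericity 0.970, compacity 11.13 (sphere: 1 and 10.63)
```

The 118-voxel ROI is the part of the nodule above 40% of its SUVmax; its
positive skewness reflects the lognormal (right-skewed) uptake model, and
the near-unit sphericity says the segmented blob is almost round.

`examples/` contains one short script per capability (phantom, segmentation
+ quantization, feature extraction, cohort screening, full pipeline), and
the `thyrotex` CLI exposes `simulate`, `extract`, `screen` and `run-all`
for shell use.

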
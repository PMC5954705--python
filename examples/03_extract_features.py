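"""Extract the full radiomic feature bank from one segmented lesion.

Conventional SUV metrics are computed on raw SUV; histogram moments and the
GLCM/NGLDM/GLRLM/GLZLM texture families on the 64-level quantized ROI; shape
descriptors from a triangulated surface.  Matrix and shape families are NaN
for ROIs under 64 voxels.
"""

from thyrotex import IntensityModel, PhantomSpec, extract_all, make_phantom, segment_nodule

grid, _, record = make_phantom(PhantomSpec(
    nodule_radii_mm=(14.0, 13.0, 13.5),
    intensity=IntensityModel("lognormal", mean=9.0, sd=2.7),
    rng_seed=11,
))
roi = segment_nodule(grid, record["center_voxel"])
features = extract_all(grid, roi)

print(f"ROI: {int(features['roi_voxel_count'])} voxels, "
      f"MTV {features['mtv_ml']:.2f} mL, TLG {features['tlg']:.1f}")
print(f"SUVmax {features['suv_max']:.2f}, SUVpeak(0.5 mL) "
      f"{features['suv_peak_0p5ml']:.2f}")
print(f"histogram skewness {features['hist_skewness']:.2f} "
      "(right-skewed uptake distribution)")
print(f"sphericity {features['shape_sphericity']:.3f}, "
      f"compacity {features['shape_compacity']:.2f} "
      "(sphere: 1 and 10.63)")
print(f"GLCM entropy {features['glcm_entropy']:.2f}, "
      f"GLRLM short-run emphasis {features['glrlm_sre']:.3f}, "
      f"GLZLM zone percentage {features['glzlm_zp']:.3f}")
# High GLCM entropy and short-run emphasis near 1 indicate a noisy,
# fine-grained texture; zone percentage near 1 means zones are tiny.
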
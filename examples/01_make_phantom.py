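"""Build a single synthetic PET phantom and compare sampled vs analytic moments.

A phantom is an ellipsoidal nodule of elevated uptake on a noisy background.
The ground-truth record carries the analytic mean/sd/skewness of the chosen
intensity model, so sampled statistics can be checked against them.
"""

import numpy as np

from thyrotex import IntensityModel, PhantomSpec, make_phantom

spec = PhantomSpec(
    grid_shape=(24, 24, 24),
    voxel_spacing=(4.0, 4.0, 4.0),          # mm
    nodule_center_mm=(48.0, 48.0, 48.0),
    nodule_radii_mm=(14.0, 12.0, 13.0),     # ellipsoid semi-axes
    intensity=IntensityModel("lognormal", mean=9.0, sd=2.7),  # right-skewed
    background_mean=1.0,
    background_sd=0.2,
    class_label="malignant",
    rng_seed=7,
)
grid, true_mask, record = make_phantom(spec)

inside = grid.values[true_mask.mask]
print(f"nodule voxels: {true_mask.voxel_count}  "
      f"(exact ellipsoid volume {record['nodule_volume_ml']:.2f} mL)")
print(f"sampled  mean/sd/skew: {inside.mean():.2f} / {inside.std():.2f} / "
      f"{float(((inside - inside.mean())**3).mean() / inside.var()**1.5):.2f}")
print(f"analytic mean/sd/skew: {record['analytic_mean']:.2f} / "
      f"{record['analytic_sd']:.2f} / {record['analytic_skewness']:.2f}")
# The sampled moments should approach the analytic ones as the nodule grows;
# the positive skewness is the asymmetry dial that separates malignant from
# benign intensity distributions in the simulated cohorts.
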
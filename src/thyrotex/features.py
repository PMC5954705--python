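"""The radiomic feature bank: conventional SUV metrics, histogram moments,
shape descriptors and the four texture-matrix families.

Conventional features are computed on raw SUV; histogram and matrix features
on the 64-level quantized ROI, mirroring tools that resample intensities
before texture computation.  Shape and matrix families are gated at 64 ROI
voxels: below that size they are NaN (not omitted), so cohort tables stay
rectangular.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .errors import FormatError
from .imaging import QuantizedRoi, RoiMask, VoxelGrid, quantize_roi, N_GRAY_LEVELS, QUANT_BOUNDS
from .texture import (
    GLCM_NAMES, GLRLM_NAMES, GLZLM_NAMES, NGLDM_NAMES, MIN_VOXELS,
    glcm_features, glrlm_features, glzlm_features, ngldm_features,
)

CONVENTIONAL_NAMES = (
    "suv_min", "suv_max", "suv_mean", "suv_std",
    "suv_peak_0p5ml", "suv_peak_1ml", "mtv_ml", "tlg",
)
HISTOGRAM_NAMES = ("hist_skewness", "hist_kurtosis", "hist_entropy", "hist_energy")
SHAPE_NAMES = ("shape_sphericity", "shape_compacity")

#: canonical column order of the feature bank
FEATURE_NAMES = (
    CONVENTIONAL_NAMES + HISTOGRAM_NAMES + SHAPE_NAMES
    + GLCM_NAMES + NGLDM_NAMES + GLRLM_NAMES + GLZLM_NAMES
)

#: families that are NaN-gated below MIN_VOXELS
GATED_NAMES = SHAPE_NAMES + GLCM_NAMES + NGLDM_NAMES + GLRLM_NAMES + GLZLM_NAMES


class PeakSphereClippedWarning(UserWarning):
    """The SUVpeak sphere extended beyond the grid; the mean was taken over
    in-grid voxels only."""


def _suv_peak(grid: VoxelGrid, center: tuple[int, int, int], volume_ml: float) -> float:
    """Mean SUV over grid voxels whose centers lie within a sphere of the
    given volume centered on ``center`` (the SUVmax voxel)."""
    radius = (3.0 * volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    sp = grid.spacing
    clipped = False
    axes = []
    for n, s, c in zip(grid.shape, sp, center):
        reach = int(math.floor(radius / s))
        lo, hi = c - reach, c + reach + 1
        if lo < 0 or hi > n:
            clipped = True
            lo, hi = max(lo, 0), min(hi, n)
        axes.append((lo, hi))
    window = grid.values[tuple(slice(lo, hi) for lo, hi in axes)]
    d0 = ((np.arange(*axes[0]) - center[0]) * sp[0]) ** 2
    d1 = ((np.arange(*axes[1]) - center[1]) * sp[1]) ** 2
    d2 = ((np.arange(*axes[2]) - center[2]) * sp[2]) ** 2
    inside = (
        d0[:, None, None] + d1[None, :, None] + d2[None, None, :]
    ) <= radius**2
    if clipped:
        warnings.warn(
            f"SUVpeak sphere ({volume_ml} mL) extends beyond the grid; "
            "averaging over in-grid voxels",
            PeakSphereClippedWarning,
            stacklevel=3,
        )
    return float(window[inside].mean())


def conventional_features(grid: VoxelGrid, mask) -> dict[str, float]:
    """SUV statistics, SUVpeak spheres, metabolic volume and lesion glycolysis.

    Moments use the population form (divisor N).  MTV is the ROI volume in
    mL; TLG = SUVmean x MTV.  SUVpeak_x is the mean SUV over grid voxels
    whose centers lie within a sphere of volume x mL centered on the SUVmax
    voxel (the sphere is not relocated).
    """
    roi = mask if isinstance(mask, RoiMask) else RoiMask(np.asarray(mask, bool), grid.spacing)
    if roi.voxel_count == 0:
        raise FormatError("empty ROI mask")
    vals = grid.values[roi.mask]
    coords = np.argwhere(roi.mask)
    peak_center = tuple(int(c) for c in coords[int(np.argmax(vals))])
    mtv = roi.volume_ml
    mean = float(vals.mean())
    return {
        "suv_min": float(vals.min()),
        "suv_max": float(vals.max()),
        "suv_mean": mean,
        "suv_std": float(vals.std()),  # population (divisor N)
        "suv_peak_0p5ml": _suv_peak(grid, peak_center, 0.5),
        "suv_peak_1ml": _suv_peak(grid, peak_center, 1.0),
        "mtv_ml": float(mtv),
        "tlg": float(mean * mtv),
    }


def histogram_features(qroi: QuantizedRoi) -> dict[str, float]:
    """Moments and uniformity of the quantized-intensity distribution.

    Skewness and kurtosis are the voxel-wise population moment ratios with
    ``a = 1/N`` (kurtosis is non-excess: a normal distribution gives ~3);
    both are NaN for a zero-variance ROI.  Entropy is ``-sum p log2 p`` and
    energy ``sum p^2`` over the 64-bin level probabilities.
    """
    x = qroi.levels.astype(np.float64)
    m = x.mean()
    m2 = ((x - m) ** 2).mean()
    if m2 == 0:
        skew = kurt = float("nan")
    else:
        skew = float(((x - m) ** 3).mean() / m2**1.5)
        kurt = float(((x - m) ** 4).mean() / m2**2)
    p = np.bincount(qroi.levels, minlength=qroi.n_bins + 1)[1:] / x.size
    pos = p > 0
    return {
        "hist_skewness": skew,
        "hist_kurtosis": kurt,
        "hist_entropy": float(-(p[pos] * np.log2(p[pos])).sum()),
        "hist_energy": float((p**2).sum()),
    }


def shape_features(mask: RoiMask, min_voxels: int = MIN_VOXELS) -> dict[str, float]:
    """Sphericity and compacity from a triangulated surface of the mask.

    The surface is the marching-cubes isosurface at 0.5 of the mask after a
    fixed 1-voxel Gaussian anti-aliasing filter (the raw staircase surface
    of a binary mask overestimates the area of a smooth boundary by ~10%
    and does not converge; the filtered isosurface does).  The mask is
    padded by two background layers so ROIs touching the grid boundary
    still close.  With A the mesh area (mm^2) and V the enclosed volume
    (mm^3)::

        sphericity = pi^(1/3) (6 V)^(2/3) / A      (1 for a perfect sphere)
        compacity  = A^(3/2) / V                   (6 sqrt(pi) for a sphere)

    NaN below the 64-voxel gate.
    """
    if mask.voxel_count < min_voxels:
        return {name: float("nan") for name in SHAPE_NAMES}
    coords = np.argwhere(mask.mask)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0) + 1
    box = mask.mask[tuple(slice(a, b) for a, b in zip(lo, hi))]
    padded = ndimage.gaussian_filter(np.pad(box, 2).astype(np.float64), 1.0)
    if padded.max() <= 0.5:
        # very thin or porous masks can be smoothed entirely below the
        # iso-level; fall back to the raw binary surface for those
        padded = np.pad(box, 2).astype(np.float64)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=mask.spacing)
    verts = verts.astype(np.float64)
    area = float(measure.mesh_surface_area(verts, faces))
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    volume = float(abs(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum()) / 6.0)
    return {
        "shape_sphericity": float(math.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / area),
        "shape_compacity": float(area**1.5 / volume),
    }


def extract_all(
    grid: VoxelGrid,
    mask,
    min_voxels: int = MIN_VOXELS,
    n_bins: int = N_GRAY_LEVELS,
    bounds: tuple[float, float] = QUANT_BOUNDS,
    return_status: bool = False,
):
    """Assemble the full feature vector for one lesion.

    Conventional and histogram features are always present; shape and the
    four matrix families are NaN when the ROI has fewer than ``min_voxels``
    voxels.  The vector additionally carries ``roi_voxel_count``.

    With ``return_status=True`` also returns a per-feature status map
    (``"ok"``, ``"gated_small_roi"`` or ``"degenerate"``).
    """
    roi = mask if isinstance(mask, RoiMask) else RoiMask(np.asarray(mask, bool), grid.spacing)
    qroi = quantize_roi(grid, roi, n_bins=n_bins, bounds=bounds)
    out: dict[str, float] = {}
    out.update(conventional_features(grid, roi))
    out.update(histogram_features(qroi))
    out.update(shape_features(roi, min_voxels=min_voxels))
    out.update(glcm_features(qroi, min_voxels=min_voxels))
    out.update(ngldm_features(qroi, min_voxels=min_voxels))
    out.update(glrlm_features(qroi, min_voxels=min_voxels))
    out.update(glzlm_features(qroi, min_voxels=min_voxels))
    out["roi_voxel_count"] = float(roi.voxel_count)
    out = {name: out[name] for name in FEATURE_NAMES + ("roi_voxel_count",)}
    if not return_status:
        return out
    gated = roi.voxel_count < min_voxels
    status = {}
    for name in FEATURE_NAMES:
        if math.isnan(out[name]):
            status[name] = "gated_small_roi" if (gated and name in GATED_NAMES) else "degenerate"
        else:
            status[name] = "ok"
    return out, status


def extract_table(lesions, subject_ids=None, **kwargs) -> pd.DataFrame:
    """Feature table over a cohort: one row per ``(grid, mask)`` lesion,
    fixed column order, NaN for gated features."""
    rows = []
    for item in lesions:
        grid, mask = item[0], item[1]
        rows.append(extract_all(grid, mask, **kwargs))
    index = subject_ids if subject_ids is not None else range(len(rows))
    df = pd.DataFrame(rows, index=pd.Index(index, name="subject_id"))
    return df
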
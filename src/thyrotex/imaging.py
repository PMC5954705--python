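"""Volumes in SUV units, lesion segmentation at a fraction of SUVmax, and
absolute gray-level quantization.

A PET volume is a 3D scalar field of standardized uptake values (SUV) with a
physical voxel spacing in mm.  Lesions are segmented by thresholding at 40% of
the local SUV maximum and keeping the 26-connected component that contains the
hottest voxel.  For texture analysis the region of interest (ROI) is resampled
onto 64 discrete gray levels spanning the absolute SUV range [0, 20].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import FormatError, SegmentationError

#: full 3D connectivity (26 neighbors) used for hot-spot growing
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

#: defaults of the analysis protocol
THRESHOLD_FRACTION = 0.40
N_GRAY_LEVELS = 64
QUANT_BOUNDS = (0.0, 20.0)


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D SUV volume with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Non-negative SUV values.
    spacing : tuple of float
        Voxel size along each axis, in mm.
    origin : tuple of float
        Physical coordinate (mm) of the corner of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise FormatError(f"expected a 3D volume, got ndim={values.ndim}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise FormatError(f"spacing must be three positive values, got {self.spacing}")
        if np.any(values < 0):
            raise FormatError("SUV values must be non-negative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (spacing is mm; 1 mL = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass(frozen=True)
class RoiMask:
    """Binary mask of a segmented nodule, congruent with its grid.

    The mask produced by :func:`segment_nodule` is a single 26-connected
    component by construction.
    """

    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 3:
            raise FormatError(f"expected a 3D mask, got ndim={mask.ndim}")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_ml(self) -> float:
        return self.voxel_count * float(np.prod(self.spacing)) / 1000.0

    def is_connected(self) -> bool:
        """True if the mask is one 26-connected component."""
        _, n = ndimage.label(self.mask, structure=STRUCT_26)
        return n == 1


@dataclass(frozen=True)
class QuantizedRoi:
    """ROI voxel intensities mapped to discrete gray levels 1..n_bins.

    ``levels`` and ``coords`` are aligned 1D/2D arrays, one entry per ROI
    voxel; ``shape`` is the shape of the parent grid.
    """

    levels: np.ndarray
    coords: np.ndarray
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    n_bins: int = N_GRAY_LEVELS
    bounds: tuple[float, float] = QUANT_BOUNDS

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=np.int64)
        coords = np.asarray(self.coords, dtype=np.int64)
        if levels.ndim != 1 or coords.shape != (levels.size, 3):
            raise FormatError("levels must be (n,) and coords (n, 3)")
        if levels.size and (levels.min() < 1 or levels.max() > self.n_bins):
            raise FormatError("gray levels must lie in [1, n_bins]")
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "coords", coords)

    @property
    def voxel_count(self) -> int:
        return int(self.levels.size)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense level array over the ROI bounding box.

        Returns ``(levels3d, mask3d, offset)`` where ``levels3d`` holds the
        gray level per voxel (0 outside the ROI), ``mask3d`` the ROI
        membership and ``offset`` the index of the box corner in the grid.
        """
        lo = self.coords.min(axis=0)
        hi = self.coords.max(axis=0) + 1
        box = np.zeros(tuple(hi - lo), dtype=np.int64)
        local = self.coords - lo
        box[tuple(local.T)] = self.levels
        return box, box > 0, lo


# ---------------------------------------------------------------------------
# NIfTI I/O

def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(grid: VoxelGrid, path) -> None:
    """Write a grid to NIfTI (.nii or .nii.gz), preserving SUV and spacing."""
    img = nib.Nifti1Image(grid.values.astype(np.float64), _affine(grid.spacing, grid.origin))
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def load_volume(path) -> VoxelGrid:
    """Read a 3D NIfTI volume into a :class:`VoxelGrid`.

    Raises :class:`FormatError` for non-3D data or invalid spacing.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # unreadable / not NIfTI
        raise FormatError(f"cannot read volume {path!r}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D volume, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return VoxelGrid(np.asarray(data, dtype=np.float64), tuple(float(z) for z in zooms), origin)


def save_mask(roi: RoiMask, path) -> None:
    """Write a binary mask as uint8 0/1 NIfTI."""
    img = nib.Nifti1Image(roi.mask.astype(np.uint8), _affine(roi.spacing, (0, 0, 0)))
    img.header.set_zooms(roi.spacing)
    nib.save(img, str(path))


def load_mask(path) -> RoiMask:
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read mask {path!r}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D mask, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    return RoiMask(data > 0, tuple(float(z) for z in zooms))


# ---------------------------------------------------------------------------
# Segmentation and quantization

def segment_nodule(
    grid: VoxelGrid,
    seed: tuple[int, int, int],
    search_radius_mm: float = 15.0,
    threshold_fraction: float = THRESHOLD_FRACTION,
) -> RoiMask:
    """Segment a hot nodule at a fraction of the local SUV maximum.

    The SUV maximum ``M`` is located within ``search_radius_mm`` (physical
    distance between voxel centers) of the seed voxel.  The ROI is the
    26-connected component of ``{SUV >= threshold_fraction * M}`` that
    contains the voxel achieving ``M``.  The seed stands in for interactive
    VOI placement: it only localizes the hot spot, the returned contour does
    not depend on its exact position within the lesion.

    Raises
    ------
    SegmentationError
        If the seed is outside the grid or no uptake (``M <= 0``) is found
        near the seed.
    """
    seed = tuple(int(s) for s in seed)
    if len(seed) != 3 or any(s < 0 or s >= n for s, n in zip(seed, grid.shape)):
        raise SegmentationError(f"seed {seed} outside grid of shape {grid.shape}")
    if not 0.0 < threshold_fraction < 1.0:
        raise SegmentationError("threshold_fraction must be in (0, 1)")

    sp = np.asarray(grid.spacing)
    axes = [
        (np.arange(n) - s) * d
        for n, s, d in zip(grid.shape, seed, sp)
    ]
    dist2 = (
        axes[0][:, None, None] ** 2
        + axes[1][None, :, None] ** 2
        + axes[2][None, None, :] ** 2
    )
    near = dist2 <= search_radius_mm ** 2
    local = np.where(near, grid.values, -np.inf)
    m = float(local.max())
    if m <= 0:
        raise SegmentationError("no uptake found near the seed (SUVmax = 0)")
    peak = np.unravel_index(int(np.argmax(local)), grid.shape)

    above = grid.values >= threshold_fraction * m
    labels, _ = ndimage.label(above, structure=STRUCT_26)
    component = labels == labels[peak]
    return RoiMask(component, grid.spacing)


def quantize_roi(
    grid: VoxelGrid,
    mask,
    n_bins: int = N_GRAY_LEVELS,
    bounds: tuple[float, float] = QUANT_BOUNDS,
) -> QuantizedRoi:
    """Resample ROI intensities onto discrete gray levels in absolute terms.

    The SUV range ``bounds`` is split into ``n_bins`` equal bins of width
    ``(hi - lo) / n_bins`` (0.3125 SUV for the default 64 bins over [0, 20]).
    A voxel with value ``v`` maps to level ``1 + floor((v - lo) / width)``,
    clipped to ``[1, n_bins]``; bins are left-closed, right-open, with the
    last bin closed through clipping.
    """
    mask_arr = mask.mask if isinstance(mask, RoiMask) else np.asarray(mask, dtype=bool)
    if mask_arr.shape != grid.shape:
        raise FormatError("mask shape does not match grid shape")
    if not mask_arr.any():
        raise FormatError("empty ROI mask")
    lo, hi = bounds
    if not hi > lo:
        raise FormatError("bounds must satisfy hi > lo")
    width = (hi - lo) / n_bins
    coords = np.argwhere(mask_arr)
    suv = grid.values[mask_arr]
    levels = 1 + np.floor((suv - lo) / width).astype(np.int64)
    np.clip(levels, 1, n_bins, out=levels)
    return QuantizedRoi(levels, coords, grid.shape, grid.spacing, n_bins, (float(lo), float(hi)))
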
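import numpy as np
import pytest

from thyrotex.imaging import QuantizedRoi, RoiMask, VoxelGrid


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_qroi(seed, shape=(5, 5, 5), n_levels=4, p_roi=0.8):
    """A small random quantized ROI plus its dense level/mask arrays."""
    r = np.random.default_rng(seed)
    mask = r.random(shape) < p_roi
    if not mask.any():
        mask[0, 0, 0] = True
    levels3d = r.integers(1, n_levels + 1, shape)
    coords = np.argwhere(mask)
    qroi = QuantizedRoi(levels3d[mask], coords, shape, (1.0, 1.0, 1.0), n_bins=64)
    return qroi, np.where(mask, levels3d, 0), mask


def sphere_mask(radius_vox, spacing=(1.0, 1.0, 1.0), margin=4):
    """Rasterized sphere (voxel-center inclusion) as a RoiMask."""
    n = int(2 * radius_vox) + 2 * margin
    ax = (np.arange(n) + 0.5) - n / 2
    d2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    return RoiMask(d2 <= radius_vox**2, spacing)


def constant_grid_roi(value=5.0, shape=(6, 6, 6), spacing=(4.0, 4.0, 4.0)):
    """A grid of constant SUV with a full-grid ROI (216 voxels >= gate)."""
    grid = VoxelGrid(np.full(shape, value), spacing)
    return grid, RoiMask(np.ones(shape, bool), spacing)
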
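"""Texture matrices and their scalar features on a quantized ROI.

Four matrix families are computed on the 64-level quantized ROI:

* GLCM — gray-level co-occurrence over the 13 unique displacement directions
  at 1-voxel distance; each directional matrix is symmetric (every voxel pair
  counted in both orders) and normalized to sum 1; scalar features are
  averaged over directions with at least one valid pair.
* NGLDM — neighborhood gray-level difference statistics between each ROI
  voxel and the mean level of its in-ROI 26-neighbors, with the classic
  coarseness (reciprocal of the intensity-weighted total difference) and
  contrast definitions.
* GLRLM — run-length matrix of maximal collinear same-level runs, per the
  same 13 directions, averaged.
* GLZLM — zone-length matrix of 26-connected same-level zones in 3D.

All families are gated: ROIs below ``min_voxels`` (64 by default) return NaN
for every feature, mirroring tools that refuse texture on tiny volumes.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .imaging import QuantizedRoi, STRUCT_26

#: unique half-space of the 26 neighbor offsets: 13 displacement directions
DIRECTIONS_13 = tuple(
    (di, dj, dk)
    for di in (-1, 0, 1)
    for dj in (-1, 0, 1)
    for dk in (-1, 0, 1)
    if (di > 0) or (di == 0 and dj > 0) or (di == 0 and dj == 0 and dk > 0)
)

MIN_VOXELS = 64
COARSENESS_CAP = 1.0e6

GLCM_NAMES = (
    "glcm_homogeneity", "glcm_energy", "glcm_contrast",
    "glcm_correlation", "glcm_entropy", "glcm_dissimilarity",
)
NGLDM_NAMES = ("ngldm_coarseness", "ngldm_contrast")
GLRLM_NAMES = (
    "glrlm_sre", "glrlm_lre", "glrlm_lgre", "glrlm_hgre", "glrlm_srlge",
    "glrlm_srhge", "glrlm_lrlge", "glrlm_lrhge", "glrlm_glnu", "glrlm_rlnu",
    "glrlm_rp",
)
GLZLM_NAMES = (
    "glzlm_sze", "glzlm_lze", "glzlm_lgze", "glzlm_hgze", "glzlm_szlge",
    "glzlm_szhge", "glzlm_lzlge", "glzlm_lzhge", "glzlm_glnu", "glzlm_zlnu",
    "glzlm_zp",
)


def _nan(names) -> dict[str, float]:
    return {n: float("nan") for n in names}


# ---------------------------------------------------------------------------
# GLCM

def _direction_pairs(box: np.ndarray, mask: np.ndarray, d):
    """Levels of co-occurring voxel pairs along displacement ``d`` (one order)."""
    sl_a, sl_b = [], []
    for n, step in zip(box.shape, d):
        if step == 0:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
        elif step == 1:
            sl_a.append(slice(0, n - 1))
            sl_b.append(slice(1, n))
        else:
            sl_a.append(slice(1, n))
            sl_b.append(slice(0, n - 1))
    sl_a, sl_b = tuple(sl_a), tuple(sl_b)
    valid = mask[sl_a] & mask[sl_b]
    return box[sl_a][valid], box[sl_b][valid]


def glcm_matrix(qroi: QuantizedRoi, direction) -> np.ndarray | None:
    """Symmetric, normalized co-occurrence matrix for one direction.

    Returns None when the direction yields no valid voxel pair.
    """
    box, mask, _ = qroi.bounding_box()
    a, b = _direction_pairs(box, mask, direction)
    if a.size == 0:
        return None
    n = qroi.n_bins
    counts = np.bincount((a - 1) * n + (b - 1), minlength=n * n).reshape(n, n).astype(np.float64)
    counts = counts + counts.T
    return counts / counts.sum()


def _glcm_scalars(p: np.ndarray) -> dict[str, float]:
    n = p.shape[0]
    i = np.arange(1, n + 1, dtype=np.float64)
    di = i[:, None] - i[None, :]
    pos = p > 0
    out = {
        "glcm_homogeneity": float((p / (1.0 + np.abs(di))).sum()),
        "glcm_energy": float((p**2).sum()),
        "glcm_contrast": float((di**2 * p).sum()),
        "glcm_entropy": float(-(p[pos] * np.log2(p[pos])).sum()),
        "glcm_dissimilarity": float((np.abs(di) * p).sum()),
    }
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((i * pi).sum())
    mu_j = float((i * pj).sum())
    sig_i = float(np.sqrt(((i - mu_i) ** 2 * pi).sum()))
    sig_j = float(np.sqrt(((i - mu_j) ** 2 * pj).sum()))
    if sig_i > 0 and sig_j > 0:
        out["glcm_correlation"] = float(
            (((i[:, None] - mu_i) * (i[None, :] - mu_j) * p).sum()) / (sig_i * sig_j)
        )
    else:
        out["glcm_correlation"] = float("nan")
    return out


def glcm_features(qroi: QuantizedRoi, min_voxels: int = MIN_VOXELS) -> dict[str, float]:
    """Direction-averaged co-occurrence features.

    Directions with no valid voxel pairs are skipped from the average;
    correlation averages only directions where both marginal variances are
    positive (a zero-variance ROI yields NaN).
    """
    if qroi.voxel_count < min_voxels:
        return _nan(GLCM_NAMES)
    per_dir: list[dict[str, float]] = []
    for d in DIRECTIONS_13:
        p = glcm_matrix(qroi, d)
        if p is not None:
            per_dir.append(_glcm_scalars(p))
    if not per_dir:
        return _nan(GLCM_NAMES)
    out = {}
    for name in GLCM_NAMES:
        vals = np.array([s[name] for s in per_dir])
        ok = ~np.isnan(vals)
        out[name] = float(vals[ok].mean()) if ok.any() else float("nan")
    return out


# ---------------------------------------------------------------------------
# NGLDM (neighborhood gray-level difference)

def ngldm_features(qroi: QuantizedRoi, min_voxels: int = MIN_VOXELS) -> dict[str, float]:
    """Coarseness and contrast from 26-neighborhood level differences.

    For each ROI voxel with at least one in-ROI neighbor, the absolute
    difference between its level and the mean level of its in-ROI
    26-neighbors is accumulated per gray level (``s_g``).  With ``p_g`` the
    fraction of counted voxels at level g and ``Ng`` the number of levels
    present::

        coarseness = 1 / sum_g p_g s_g          (capped at 1e6)
        contrast   = [sum_{g1,g2} p_g1 p_g2 (g1-g2)^2 / (Ng (Ng-1))]
                     * [sum_g s_g / N]

    A homogeneous ROI has total difference 0: coarseness returns the cap and
    contrast 0.
    """
    if qroi.voxel_count < min_voxels:
        return _nan(NGLDM_NAMES)
    box, mask, _ = qroi.bounding_box()
    maskf = mask.astype(np.float64)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nbr_cnt = ndimage.convolve(maskf, kernel, mode="constant")
    nbr_sum = ndimage.convolve(box * maskf, kernel, mode="constant")
    counted = mask & (nbr_cnt > 0)
    lev = box[counted]
    diff = np.abs(lev - nbr_sum[counted] / nbr_cnt[counted])

    nb = qroi.n_bins
    s = np.bincount(lev - 1, weights=diff, minlength=nb)
    n_g = np.bincount(lev - 1, minlength=nb).astype(np.float64)
    n_tot = n_g.sum()
    p = n_g / n_tot
    present = p > 0
    n_levels = int(present.sum())

    denom = float((p * s).sum())
    coarseness = COARSENESS_CAP if denom == 0 else min(1.0 / denom, COARSENESS_CAP)
    if n_levels < 2:
        contrast = 0.0
    else:
        g = np.arange(1, nb + 1, dtype=np.float64)
        dg2 = (g[:, None] - g[None, :]) ** 2
        pairs = float((p[:, None] * p[None, :] * dg2).sum())
        contrast = pairs / (n_levels * (n_levels - 1)) * float(s.sum()) / n_tot
    return {"ngldm_coarseness": float(coarseness), "ngldm_contrast": float(contrast)}


# ---------------------------------------------------------------------------
# Shared run/zone statistics

def _size_stats(levels: np.ndarray, sizes: np.ndarray, n_voxels: int, names) -> dict[str, float]:
    """The 11 emphasis/non-uniformity/percentage statistics over (level, size)
    elements (runs or zones), each element counted once."""
    g = levels.astype(np.float64)
    s = sizes.astype(np.float64)
    n = float(g.size)
    by_level = np.bincount(levels)
    by_size = np.bincount(sizes)
    vals = (
        float((1.0 / s**2).sum() / n),            # short emphasis
        float((s**2).sum() / n),                  # long emphasis
        float((1.0 / g**2).sum() / n),            # low gray-level
        float((g**2).sum() / n),                  # high gray-level
        float((1.0 / (g**2 * s**2)).sum() / n),   # short + low
        float((g**2 / s**2).sum() / n),           # short + high
        float((s**2 / g**2).sum() / n),           # long + low
        float((g**2 * s**2).sum() / n),           # long + high
        float((by_level.astype(np.float64) ** 2).sum() / n),  # gray-level non-uniformity
        float((by_size.astype(np.float64) ** 2).sum() / n),   # size non-uniformity
        float(n / n_voxels),                      # percentage
    )
    return dict(zip(names, vals))


# ---------------------------------------------------------------------------
# GLRLM

def run_lengths(qroi: QuantizedRoi, direction) -> tuple[np.ndarray, np.ndarray]:
    """Maximal same-level runs of in-ROI collinear voxels along a direction.

    Returns ``(levels, lengths)``, one entry per run.  Runs break at the ROI
    boundary and at level changes.
    """
    d = np.asarray(direction, dtype=np.int64)
    coords = qroi.coords
    levels = qroi.levels
    ax = int(np.flatnonzero(d)[0])
    sign = int(d[ax])
    t = coords[:, ax] * sign  # step index: increments by 1 per hop along d
    line_key = coords - t[:, None] * d[None, :]
    order = np.lexsort((t, line_key[:, 2], line_key[:, 1], line_key[:, 0]))
    t_s = t[order]
    lk_s = line_key[order]
    lv_s = levels[order]
    n = lv_s.size
    breaks = np.empty(n, dtype=bool)
    breaks[0] = True
    breaks[1:] = (
        np.any(lk_s[1:] != lk_s[:-1], axis=1)
        | (t_s[1:] != t_s[:-1] + 1)
        | (lv_s[1:] != lv_s[:-1])
    )
    starts = np.flatnonzero(breaks)
    lengths = np.diff(np.append(starts, n))
    return lv_s[starts], lengths


def glrlm_features(qroi: QuantizedRoi, min_voxels: int = MIN_VOXELS) -> dict[str, float]:
    """Run-length features averaged over the 13 directions."""
    if qroi.voxel_count < min_voxels:
        return _nan(GLRLM_NAMES)
    acc = {name: [] for name in GLRLM_NAMES}
    for d in DIRECTIONS_13:
        lv, ln = run_lengths(qroi, d)
        stats = _size_stats(lv, ln, qroi.voxel_count, GLRLM_NAMES)
        for name, v in stats.items():
            acc[name].append(v)
    return {name: float(np.mean(vs)) for name, vs in acc.items()}


# ---------------------------------------------------------------------------
# GLZLM

def zone_sizes(qroi: QuantizedRoi) -> tuple[np.ndarray, np.ndarray]:
    """26-connected same-level zones: ``(levels, sizes)``, one entry per zone."""
    box, mask, _ = qroi.bounding_box()
    zl, zs = [], []
    for g in np.unique(qroi.levels):
        lab, n = ndimage.label(box == g, structure=STRUCT_26)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            zl.append(np.full(n, g, dtype=np.int64))
            zs.append(sizes.astype(np.int64))
    return np.concatenate(zl), np.concatenate(zs)


def glzlm_features(qroi: QuantizedRoi, min_voxels: int = MIN_VOXELS) -> dict[str, float]:
    """Zone-length features (single 3D zone matrix; no direction average)."""
    if qroi.voxel_count < min_voxels:
        return _nan(GLZLM_NAMES)
    lv, sz = zone_sizes(qroi)
    return _size_stats(lv, sz, qroi.voxel_count, GLZLM_NAMES)
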
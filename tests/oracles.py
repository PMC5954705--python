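"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (python loops, explicit enumeration,
BFS flood fill) and shares no code path with the package implementation.
"""

import itertools
from math import comb

import numpy as np

OFFSETS_26 = [
    np.array(o) for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)
]


# ---------------------------------------------------------------------------
# Texture


def glcm_matrix(levels3d, mask, direction, n_levels=64):
    """Symmetric normalized co-occurrence matrix by explicit pair walking."""
    d = np.asarray(direction)
    voxels = {tuple(v): levels3d[tuple(v)] for v in np.argwhere(mask)}
    c = np.zeros((n_levels, n_levels))
    for v, g in voxels.items():
        w = tuple(np.array(v) + d)
        if w in voxels:
            h = voxels[w]
            c[g - 1, h - 1] += 1
            c[h - 1, g - 1] += 1
    total = c.sum()
    return c / total if total else None


def glcm_scalars(p):
    n = p.shape[0]
    out = dict.fromkeys(
        ["homogeneity", "energy", "contrast", "entropy", "dissimilarity"], 0.0
    )
    for i in range(n):
        for j in range(n):
            if p[i, j] == 0 and i != j:
                pass
            out["homogeneity"] += p[i, j] / (1 + abs(i - j))
            out["energy"] += p[i, j] ** 2
            out["contrast"] += (i - j) ** 2 * p[i, j]
            out["dissimilarity"] += abs(i - j) * p[i, j]
            if p[i, j] > 0:
                out["entropy"] -= p[i, j] * np.log2(p[i, j])
    i = np.arange(1, n + 1)
    pi, pj = p.sum(1), p.sum(0)
    mu_i, mu_j = (i * pi).sum(), (i * pj).sum()
    si = np.sqrt(((i - mu_i) ** 2 * pi).sum())
    sj = np.sqrt(((i - mu_j) ** 2 * pj).sum())
    if si > 0 and sj > 0:
        out["correlation"] = float(
            ((i[:, None] - mu_i) * (i[None, :] - mu_j) * p).sum() / (si * sj)
        )
    else:
        out["correlation"] = float("nan")
    return out


def runs(levels3d, mask, direction):
    """All maximal same-level in-mask runs along one direction."""
    d = np.asarray(direction)
    voxels = {tuple(v): levels3d[tuple(v)] for v in np.argwhere(mask)}
    found = []
    for v, g in voxels.items():
        prev = tuple(np.array(v) - d)
        if prev in voxels and voxels[prev] == g:
            continue  # not a run start
        length, cur = 1, np.array(v)
        while True:
            nxt = tuple(cur + d)
            if nxt in voxels and voxels[nxt] == g:
                length += 1
                cur = np.array(nxt)
            else:
                break
        found.append((g, length))
    return sorted(found)


def zones(levels3d, mask):
    """26-connected same-level zones by BFS flood fill."""
    voxels = {tuple(v): levels3d[tuple(v)] for v in np.argwhere(mask)}
    seen, out = set(), []
    for v in sorted(voxels):
        if v in seen:
            continue
        g = voxels[v]
        stack, size = [v], 0
        seen.add(v)
        while stack:
            c = stack.pop()
            size += 1
            for o in OFFSETS_26:
                w = tuple(np.array(c) + o)
                if w in voxels and w not in seen and voxels[w] == g:
                    seen.add(w)
                    stack.append(w)
        out.append((g, size))
    return sorted(out)


def size_stats(elements, n_voxels):
    """The 11 run/zone statistics from a list of (level, size) elements."""
    g = np.array([e[0] for e in elements], dtype=float)
    s = np.array([e[1] for e in elements], dtype=float)
    n = len(elements)
    by_g = {}
    by_s = {}
    for gi, si in elements:
        by_g[gi] = by_g.get(gi, 0) + 1
        by_s[si] = by_s.get(si, 0) + 1
    return {
        "short": (1 / s**2).sum() / n,
        "long": (s**2).sum() / n,
        "low": (1 / g**2).sum() / n,
        "high": (g**2).sum() / n,
        "short_low": (1 / (g**2 * s**2)).sum() / n,
        "short_high": (g**2 / s**2).sum() / n,
        "long_low": (s**2 / g**2).sum() / n,
        "long_high": (g**2 * s**2).sum() / n,
        "gnu": sum(c**2 for c in by_g.values()) / n,
        "snu": sum(c**2 for c in by_s.values()) / n,
        "pct": n / n_voxels,
    }


def ngldm(levels3d, mask, n_levels=64, cap=1.0e6):
    """Neighborhood gray-level difference coarseness/contrast by direct loops."""
    voxels = {tuple(v): levels3d[tuple(v)] for v in np.argwhere(mask)}
    s = np.zeros(n_levels)
    ng = np.zeros(n_levels)
    for v, g in voxels.items():
        nb = [voxels[tuple(np.array(v) + o)] for o in OFFSETS_26 if tuple(np.array(v) + o) in voxels]
        if not nb:
            continue
        s[g - 1] += abs(g - np.mean(nb))
        ng[g - 1] += 1
    n_tot = ng.sum()
    p = ng / n_tot
    n_present = int((p > 0).sum())
    denom = float((p * s).sum())
    coarseness = cap if denom == 0 else min(1.0 / denom, cap)
    if n_present < 2:
        contrast = 0.0
    else:
        gl = np.arange(1, n_levels + 1)
        pairs = float((p[:, None] * p[None, :] * (gl[:, None] - gl[None, :]) ** 2).sum())
        contrast = pairs / (n_present * (n_present - 1)) * s.sum() / n_tot
    return coarseness, contrast


# ---------------------------------------------------------------------------
# Statistics


def auc_pairs(values, labels):
    """AUC by exhaustive pair comparison, ties counted 1/2."""
    pos = [v for v, y in zip(values, labels) if y == 1]
    neg = [v for v, y in zip(values, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def fisher_two_sided(tp, fp, fn, tn):
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    r1, r2 = tp + fp, fn + tn
    c1 = tp + fn
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0

    def prob(k):
        if k < 0 or k > r1 or c1 - k < 0 or c1 - k > r2:
            return 0.0
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

    p_obs = prob(tp)
    return sum(prob(k) for k in range(c1 + 1) if prob(k) <= p_obs * (1 + 1e-7))


def best_split(values, labels):
    """Exhaustive evaluation of every possible dichotomizing split.

    Mirrors the contract: candidate thresholds are midpoints between
    consecutive sorted distinct values, positive call at value >= threshold,
    minimal two-sided Fisher p, ties broken by max Youden's J then smaller
    threshold.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    distinct = np.unique(v)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    best = None
    for a, b in zip(distinct[:-1], distinct[1:]):
        t = (a + b) / 2
        tp = int(((v >= t) & (y == 1)).sum())
        fp = int(((v >= t) & (y == 0)).sum())
        p = fisher_two_sided(tp, fp, n_pos - tp, n_neg - fp)
        j = tp / n_pos + (n_neg - fp) / n_neg - 1
        key = (float(f"{p:.12e}"), -j, t)
        if best is None or key < best[0]:
            best = (key, (t, p, tp, fp, n_pos - tp, n_neg - fp))
    return best[1]


def pearson_r(x, y):
    """Textbook covariance / (sigma sigma) with population divisors."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return cov / (x.std() * y.std())
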
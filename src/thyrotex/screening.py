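"""Predictor screening: group comparison, ROC pre-selection, correlation
audit, Fisher-optimal dichotomization and predictive scoring.

The workflow mirrors a univariate screening protocol for a binary outcome
(benign vs malignant):

1. each feature is compared across cytology categories and across the final
   diagnosis with a one-way ANOVA;
2. the ROC AUC of each feature is computed (rank formulation, ties counted
   1/2) and features with oriented AUC < 0.55 are excluded;
3. mutual Pearson correlation among the pre-selected features is reported
   (flagged at the 0.01 level) but no feature is removed for redundancy;
4. each pre-selected feature is dichotomized at the threshold minimizing the
   two-sided Fisher exact p-value; features with p < 0.08 form the final set;
5. the truth table at the optimal cutoff yields sensitivity, specificity,
   PPV and NPV; PPV/NPV are averaged over the final set.

No multiple-testing correction is applied: the features are screened
univariately, uncorrected, which inflates optimism — a caveat carried in the
report rather than fixed here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError

AUC_MIN = 0.55
FISHER_ALPHA = 0.08
ANOVA_ALPHA = 0.05
N_BOOT = 2000


# ---------------------------------------------------------------------------
# Elementary statistics

def anova_oneway(groups) -> tuple[float, float]:
    """Classical one-way ANOVA.

    Parameters
    ----------
    groups : sequence of 1D arrays
        Observations per group; NaN values are dropped.

    Returns
    -------
    (F, p) with p from the upper tail of the F distribution.  If every group
    mean is equal and the within-group variance is zero, returns (0, 1).
    """
    cleaned = [np.asarray(g, dtype=np.float64) for g in groups]
    cleaned = [g[~np.isnan(g)] for g in cleaned]
    if len(cleaned) < 2:
        raise ParameterError("ANOVA needs at least two groups")
    if any(g.size == 0 for g in cleaned):
        raise ParameterError("every group must be nonempty after NaN removal")
    n = sum(g.size for g in cleaned)
    k = len(cleaned)
    if n <= k:
        raise ParameterError("total sample size must exceed the number of groups")
    grand = np.concatenate(cleaned).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in cleaned)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in cleaned)
    if ssw == 0:
        if ssb == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ssb / (k - 1)) / (ssw / (n - k))
    p = float(stats.f.sf(f, k - 1, n - k))
    return float(f), p


def _auc_rank(values: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) formulation with ties counted 1/2."""
    ranks = stats.rankdata(values)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass(frozen=True)
class RocResult:
    auc: float
    orientation: int          # +1: larger values indicate malignancy
    ci_low: float
    ci_high: float


def roc_auc(values, labels, n_boot: int = N_BOOT, seed: int = 0) -> RocResult:
    """Oriented ROC AUC with a stratified-bootstrap 95% CI.

    NaN observations are dropped pairwise.  When the raw AUC is below 0.5
    the feature sign is flipped (orientation -1) and the flipped AUC is
    reported, so "positive" always means "toward malignancy".  The CI is the
    2.5/97.5 percentile interval over ``n_boot`` within-class resamples.
    """
    v = np.asarray(values, dtype=np.float64)
    y = np.asarray(labels)
    keep = ~np.isnan(v)
    v, y = v[keep], y[keep]
    y = y.astype(np.int64)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ParameterError("both classes must be present")
    raw = _auc_rank(v, y)
    orientation = 1 if raw >= 0.5 else -1
    ov = v * orientation
    auc = raw if orientation == 1 else 1.0 - raw

    rng = np.random.default_rng(seed)
    pos, neg = ov[y == 1], ov[y == 0]
    bp = pos[rng.integers(0, n1, (n_boot, n1))]
    bn = neg[rng.integers(0, n0, (n_boot, n0))]
    cmp_ = bp[:, :, None] - bn[:, None, :]
    aucs = ((cmp_ > 0).sum(axis=(1, 2)) + 0.5 * (cmp_ == 0).sum(axis=(1, 2))) / (n1 * n0)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return RocResult(float(auc), orientation, float(lo), float(hi))


def preselect(aucs: dict[str, float], auc_min: float = AUC_MIN) -> list[str]:
    """Keep features whose oriented AUC is at least ``auc_min`` (the
    boundary is inclusive: only AUC < auc_min are excluded)."""
    return [name for name, a in aucs.items() if not math.isnan(a) and a >= auc_min]


def correlation_audit(
    table: pd.DataFrame, subset=None, alpha: float = 0.01
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation on pairwise-complete rows.

    Returns ``(r, p, flagged)`` DataFrames; ``flagged`` marks pairs whose
    two-sided t-test p-value falls below ``alpha``.  Pairs with fewer than 3
    complete rows or a constant feature get NaN.
    """
    cols = list(subset) if subset is not None else list(table.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            x = table[cols[i]].to_numpy(dtype=np.float64)
            y = table[cols[j]].to_numpy(dtype=np.float64)
            keep = ~(np.isnan(x) | np.isnan(y))
            if keep.sum() < 3:
                continue
            xs, ys = x[keep], y[keep]
            if xs.std() == 0 or ys.std() == 0:
                continue
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
            else:
                res = stats.pearsonr(xs, ys)
                r[i, j] = r[j, i] = float(res.statistic)
                p[i, j] = p[j, i] = float(res.pvalue)
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    flagged = (pdf < alpha) & ~np.eye(k, dtype=bool)
    return rdf, pdf, pd.DataFrame(flagged, index=cols, columns=cols)


def fisher_exact_2x2(tp: int, fp: int, fn: int, tn: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[tp, fp], [fn, tn]].

    Any zero margin gives p = 1.
    """
    if min(tp, fp, fn, tn) < 0:
        raise ParameterError("cell counts must be non-negative")
    if tp + fp + fn + tn == 0:
        raise ParameterError("the table must have a positive grand total")
    return float(stats.fisher_exact([[tp, fp], [fn, tn]], alternative="two-sided")[1])


@dataclass(frozen=True)
class DichotomyResult:
    threshold: float          # on the oriented scale: predict positive if oriented value >= threshold
    fisher_p: float
    tp: int
    fp: int
    fn: int
    tn: int


def optimal_dichotomization(values, labels, orientation: int = 1) -> DichotomyResult:
    """Dichotomize a feature at the threshold minimizing the Fisher exact p.

    Candidate thresholds are the midpoints between consecutive sorted
    distinct (oriented) values; a case is called positive when its oriented
    value is at or above the threshold.  Ties on the minimal p are broken
    toward the threshold maximizing Youden's J, then toward the smaller
    threshold.
    """
    v = np.asarray(values, dtype=np.float64) * orientation
    y = np.asarray(labels).astype(np.int64)
    keep = ~np.isnan(v)
    v, y = v[keep], y[keep]
    if y.sum() == 0 or y.sum() == y.size:
        raise ParameterError("both classes must be present")
    distinct = np.unique(v)
    if distinct.size < 2:
        raise ParameterError("need at least two distinct values to split")
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    best = None
    for t in mids:
        pred = v >= t
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        fn = n_pos - tp
        tn = n_neg - fp
        p = fisher_exact_2x2(tp, fp, fn, tn)
        youden = tp / n_pos + tn / n_neg - 1.0
        # ties on p are detected to 12 significant digits so that
        # mathematically equal tables compare equal despite float noise
        key = (float(f"{p:.12e}"), -youden, t)
        if best is None or key < best[0]:
            best = (key, DichotomyResult(float(t), p, tp, fp, fn, tn))
    return best[1]


def predictive_scores(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """Sensitivity, specificity, PPV and NPV in percent (full precision;
    zero denominators give NaN)."""
    def ratio(a, b):
        return 100.0 * a / b if b > 0 else float("nan")
    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


def truth_table_from_rates(
    sens_pct: float, spec_pct: float, n_pos: int, n_neg: int
) -> tuple[int, int, int, int]:
    """Reconstruct the integer confusion matrix behind rounded sensitivity
    and specificity percentages and known class counts.

    Picks the integer TP (resp. TN) whose exact percentage is closest to the
    printed value.  Returns ``(tp, fp, fn, tn)``.
    """
    tp = int(np.argmin([abs(100.0 * t / n_pos - sens_pct) for t in range(n_pos + 1)]))
    tn = int(np.argmin([abs(100.0 * t / n_neg - spec_pct) for t in range(n_neg + 1)]))
    return tp, n_neg - tn, n_pos - tp, tn


# ---------------------------------------------------------------------------
# Whole-cohort screening


@dataclass
class PredictorResult:
    """Per-feature screening outcome (percentages in full precision)."""

    feature: str
    n_used: int
    orientation: int
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    anova_f_tir: float
    anova_p_tir: float
    anova_f_diagnosis: float
    anova_p_diagnosis: float
    preselected: bool
    best_threshold: float = float("nan")
    fisher_p: float = float("nan")
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    ppv: float = float("nan")
    npv: float = float("nan")


@dataclass
class ScreeningReport:
    """Aggregate result of the screening workflow over a feature table."""

    results: dict[str, PredictorResult]
    preselected: list[str]
    final: list[str]
    not_evaluable: list[str]
    correlation_r: pd.DataFrame
    correlation_p: pd.DataFrame
    correlation_flagged: pd.DataFrame
    average_ppv: float
    average_npv: float
    settings: dict = field(default_factory=dict)

    def predictors_table(self) -> pd.DataFrame:
        """Per-feature AUC/threshold/p summary (one row per feature)."""
        rows = [asdict(r) for r in self.results.values()]
        return pd.DataFrame(rows).set_index("feature")

    def scores_table(self, rounded: bool = True) -> pd.DataFrame:
        """Truth tables and predictive scores of the final predictors,
        percentages rounded to integers for reporting."""
        rows = []
        for name in self.final:
            r = self.results[name]
            row = {
                "feature": name, "tp": r.tp, "fp": r.fp, "fn": r.fn, "tn": r.tn,
                "sensitivity": r.sensitivity, "specificity": r.specificity,
                "ppv": r.ppv, "npv": r.npv,
            }
            if rounded:
                for k in ("sensitivity", "specificity", "ppv", "npv"):
                    row[k] = int(round(row[k])) if not math.isnan(row[k]) else row[k]
            rows.append(row)
        return pd.DataFrame(rows, columns=[
            "feature", "tp", "fp", "fn", "tn",
            "sensitivity", "specificity", "ppv", "npv",
        ]).set_index("feature") if rows else pd.DataFrame(
            columns=["tp", "fp", "fn", "tn", "sensitivity", "specificity", "ppv", "npv"]
        )

    def to_json(self) -> str:
        payload = {
            "settings": self.settings,
            "preselected": self.preselected,
            "final": self.final,
            "not_evaluable": self.not_evaluable,
            "average_ppv": self.average_ppv,
            "average_npv": self.average_npv,
            "caveat": "univariate screening without multiple-testing correction",
            "results": {k: asdict(v) for k, v in self.results.items()},
            "correlation_r": json.loads(self.correlation_r.to_json(orient="split")),
        }

        def clean(o):
            if isinstance(o, float) and math.isnan(o):
                return None
            if isinstance(o, dict):
                return {k: clean(v) for k, v in o.items()}
            if isinstance(o, list):
                return [clean(v) for v in o]
            return o

        return json.dumps(clean(payload), indent=2)


def screen(
    features: pd.DataFrame,
    labels,
    tir=None,
    auc_min: float = AUC_MIN,
    fisher_alpha: float = FISHER_ALPHA,
    anova_alpha: float = ANOVA_ALPHA,
    n_boot: int = N_BOOT,
    seed: int = 0,
) -> ScreeningReport:
    """Run the full screening workflow over a cohort feature table.

    Parameters
    ----------
    features : DataFrame
        One row per subject, one column per feature (NaN allowed, e.g. for
        size-gated matrix features).
    labels : array-like of {"benign", "malignant"} or {0, 1}
        Final diagnosis per subject.
    tir : array-like of str, optional
        Five-level cytology category per subject for the ANOVA-by-category
        comparison.
    """
    y = np.asarray(labels)
    if y.dtype.kind in "SUO":
        y = (y == "malignant").astype(np.int64)
    else:
        y = y.astype(np.int64)
    tir_arr = np.asarray(tir) if tir is not None else None

    feature_cols = [c for c in features.columns if c != "roi_voxel_count"]
    results: dict[str, PredictorResult] = {}
    not_evaluable: list[str] = []
    rng = np.random.default_rng(seed)
    for name in feature_cols:
        v = features[name].to_numpy(dtype=np.float64)
        keep = ~np.isnan(v)
        if keep.sum() < 3 or len(np.unique(y[keep])) < 2 or np.unique(v[keep]).size < 2:
            not_evaluable.append(name)
            continue
        boot_seed = int(rng.integers(0, 2**31 - 1))
        roc = roc_auc(v, y, n_boot=n_boot, seed=boot_seed)
        f_diag, p_diag = anova_oneway([v[keep][y[keep] == 0], v[keep][y[keep] == 1]])
        if tir_arr is not None:
            groups = [
                v[keep][tir_arr[keep] == cat]
                for cat in np.unique(tir_arr[keep])
            ]
            groups = [g[~np.isnan(g)] for g in groups]
            groups = [g for g in groups if g.size > 0]
            if len(groups) >= 2 and sum(g.size for g in groups) > len(groups):
                f_tir, p_tir = anova_oneway(groups)
            else:
                f_tir, p_tir = float("nan"), float("nan")
        else:
            f_tir, p_tir = float("nan"), float("nan")
        results[name] = PredictorResult(
            feature=name,
            n_used=int(keep.sum()),
            orientation=roc.orientation,
            auc=roc.auc,
            auc_ci_low=roc.ci_low,
            auc_ci_high=roc.ci_high,
            anova_f_tir=f_tir,
            anova_p_tir=p_tir,
            anova_f_diagnosis=f_diag,
            anova_p_diagnosis=p_diag,
            preselected=roc.auc >= auc_min,
        )

    kept = preselect({n: r.auc for n, r in results.items()}, auc_min=auc_min)
    for name in results:
        results[name].preselected = name in kept

    corr_r, corr_p, corr_flag = (
        correlation_audit(features, kept) if kept
        else (pd.DataFrame(), pd.DataFrame(), pd.DataFrame())
    )

    final: list[str] = []
    for name in kept:
        r = results[name]
        v = features[name].to_numpy(dtype=np.float64)
        dich = optimal_dichotomization(v, y, orientation=r.orientation)
        scores = predictive_scores(dich.tp, dich.fp, dich.fn, dich.tn)
        r.best_threshold = dich.threshold
        r.fisher_p = dich.fisher_p
        r.tp, r.fp, r.fn, r.tn = dich.tp, dich.fp, dich.fn, dich.tn
        r.sensitivity = scores["sensitivity"]
        r.specificity = scores["specificity"]
        r.ppv = scores["ppv"]
        r.npv = scores["npv"]
        if dich.fisher_p < fisher_alpha:
            final.append(name)

    ppvs = [results[n].ppv for n in final if not math.isnan(results[n].ppv)]
    npvs = [results[n].npv for n in final if not math.isnan(results[n].npv)]
    return ScreeningReport(
        results=results,
        preselected=kept,
        final=final,
        not_evaluable=not_evaluable,
        correlation_r=corr_r,
        correlation_p=corr_p,
        correlation_flagged=corr_flag,
        average_ppv=float(np.mean([round(x) for x in ppvs])) if ppvs else float("nan"),
        average_npv=float(np.mean([round(x) for x in npvs])) if npvs else float("nan"),
        settings={
            "auc_min": auc_min,
            "fisher_alpha": fisher_alpha,
            "anova_alpha": anova_alpha,
            "n_boot": n_boot,
            "seed": seed,
        },
    )
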
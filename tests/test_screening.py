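import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from sklearn.metrics import roc_auc_score

import oracles
from thyrotex.errors import ParameterError
from thyrotex.screening import (
    anova_oneway, correlation_audit, fisher_exact_2x2, optimal_dichotomization,
    predictive_scores, preselect, roc_auc, screen, truth_table_from_rates,
)


class TestAnova:
    def test_identical_groups(self):
        f, p = anova_oneway([[1, 2, 3], [1, 2, 3]])
        assert f == 0.0 and p == 1.0

    def test_hand_computed_f(self):
        f, p = anova_oneway([[1, 2], [3, 4]])
        assert f == pytest.approx(8.0)  # SSB 4, SSW 1, df (1, 2)
        assert p == pytest.approx(stats.f.sf(8.0, 1, 2))

    def test_two_groups_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        f, p = anova_oneway([a, b])
        t, pt = stats.ttest_ind(a, b)  # pooled-variance t
        assert f == pytest.approx(t**2)
        assert p == pytest.approx(pt)

    def test_matches_scipy_multi_group(self, rng):
        groups = [rng.normal(m, 1, n) for m, n in [(0, 8), (0.5, 12), (1, 6), (0, 9)]]
        f, p = anova_oneway(groups)
        ref = stats.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_nan_dropped_and_empty_group_rejected(self):
        f, _ = anova_oneway([[1, 2, np.nan], [3, 4]])
        f2, _ = anova_oneway([[1, 2], [3, 4]])
        assert f == pytest.approx(f2)
        with pytest.raises(ParameterError):
            anova_oneway([[np.nan, np.nan], [1, 2]])

    def test_zero_within_variance_separated_means(self):
        f, p = anova_oneway([[1, 1], [2, 2]])
        assert math.isinf(f) and p == 0.0


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3, 4], [0, 0, 1, 1], n_boot=10)
        assert r.auc == 1.0 and r.orientation == 1

    def test_all_ties(self):
        r = roc_auc([5, 5, 5, 5], [0, 1, 0, 1], n_boot=10)
        assert r.auc == 0.5

    def test_orientation_flip(self):
        r = roc_auc([4, 3, 2, 1], [0, 0, 1, 1], n_boot=10)
        assert r.auc == 1.0 and r.orientation == -1

    def test_matches_pair_counting_oracle(self, rng):
        values = np.round(rng.normal(0, 1, 200), 1)  # rounding creates ties
        labels = (rng.random(200) < 0.4).astype(int)
        r = roc_auc(values, labels, n_boot=10)
        raw = oracles.auc_pairs(values, labels)
        assert r.auc == pytest.approx(max(raw, 1 - raw), abs=1e-12)

    def test_matches_sklearn(self, rng):
        values = rng.normal(0, 1, 150)
        labels = (rng.random(150) < 0.5).astype(int)
        r = roc_auc(values, labels, n_boot=10)
        ref = roc_auc_score(labels, values)
        assert r.auc == pytest.approx(max(ref, 1 - ref), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        values = rng.normal(2, 1, 80)
        labels = (rng.random(80) < 0.4).astype(int)
        a1 = roc_auc(values, labels, n_boot=10).auc
        a2 = roc_auc(np.exp(values), labels, n_boot=10).auc
        a3 = roc_auc(3 * values - 7, labels, n_boot=10).auc
        assert a1 == pytest.approx(a2) == pytest.approx(a3)

    def test_ci_brackets_auc_and_is_seeded(self, rng):
        values = rng.normal(0, 1, 60) + 0.8 * (y := (rng.random(60) < 0.4).astype(int))
        r1 = roc_auc(values, y, n_boot=500, seed=7)
        r2 = roc_auc(values, y, n_boot=500, seed=7)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        assert r1.ci_low <= r1.auc <= r1.ci_high

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            roc_auc([1, 2, 3], [1, 1, 1], n_boot=10)


class TestPreselect:
    def test_boundary_inclusive(self):
        kept = preselect({"a": 0.55, "b": 0.54, "c": 0.90, "d": float("nan")})
        assert kept == ["a", "c"]

    def test_empty(self):
        assert preselect({}) == []


class TestCorrelationAudit:
    def test_diagonal_and_affine(self, rng):
        x = rng.normal(0, 1, 20)
        df = pd.DataFrame({"x": x, "y": 2 * x + 3, "z": rng.normal(0, 1, 20)})
        r, p, flagged = correlation_audit(df)
        assert r.loc["x", "x"] == 1.0
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert flagged.loc["x", "y"]
        assert not flagged.loc["x", "x"]  # diagonal never flagged

    def test_matches_hand_oracle(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (10, 2)), columns=["a", "b"])
        r, _, _ = correlation_audit(df)
        assert r.loc["a", "b"] == pytest.approx(oracles.pearson_r(df["a"], df["b"]))

    def test_pairwise_complete_and_constant(self, rng):
        df = pd.DataFrame({
            "a": [1, 2, 3, 4, np.nan, 6],
            "b": [2, 4, 6, 8, 10, np.nan],
            "c": [5, 5, 5, 5, 5, 5],
        })
        r, _, _ = correlation_audit(df)
        assert r.loc["a", "b"] == pytest.approx(1.0)  # complete rows are affine
        assert math.isnan(r.loc["a", "c"])


class TestFisher:
    def test_diagonal_table(self):
        assert fisher_exact_2x2(5, 0, 0, 5) == pytest.approx(2 / 252, rel=1e-10)

    def test_flat_table(self):
        assert fisher_exact_2x2(1, 1, 1, 1) == 1.0

    def test_zero_margin(self):
        assert fisher_exact_2x2(0, 0, 3, 4) == 1.0

    def test_matches_enumeration_all_margins_le_8(self):
        for tp, fp, fn, tn in itertools.product(range(5), repeat=4):
            if tp + fp + fn + tn == 0:
                continue
            mine = fisher_exact_2x2(tp, fp, fn, tn)
            ref = oracles.fisher_two_sided(tp, fp, fn, tn)
            assert mine == pytest.approx(ref, rel=1e-7), (tp, fp, fn, tn)


class TestOptimalDichotomization:
    def test_separable_reaches_diagonal_fisher_p(self):
        values = [1, 2, 3, 10, 11, 12]
        labels = [0, 0, 0, 1, 1, 1]
        d = optimal_dichotomization(values, labels)
        assert d.fp == d.fn == 0
        assert d.fisher_p == pytest.approx(oracles.fisher_two_sided(3, 0, 0, 3))
        assert 3 < d.threshold < 10

    def test_matches_exhaustive_search_small_n(self, rng):
        for trial in range(60):
            n = int(rng.integers(4, 9))
            values = np.round(rng.normal(0, 1, n), 1)
            labels = rng.permutation([1] * (n // 2) + [0] * (n - n // 2))
            if np.unique(values).size < 2:
                continue
            d = optimal_dichotomization(values, labels)
            t, p, tp, fp, fn, tn = oracles.best_split(values, labels)
            assert d.threshold == pytest.approx(t)
            assert d.fisher_p == pytest.approx(p, rel=1e-7)
            assert (d.tp, d.fp, d.fn, d.tn) == (tp, fp, fn, tn)

    def test_minimized_p_is_optimistic_under_null(self, rng):
        # with labels independent of values, the threshold-optimized p is
        # stochastically smaller than the p at a fixed median split
        values = rng.normal(0, 1, 40)
        labels = np.array([1] * 20 + [0] * 20)
        min_ps, fixed_ps = [], []
        med = np.median(values)
        for _ in range(200):
            perm = rng.permutation(labels)
            min_ps.append(optimal_dichotomization(values, perm).fisher_p)
            pred = values >= med
            tp = int((pred & (perm == 1)).sum())
            fp = int((pred & (perm == 0)).sum())
            fixed_ps.append(fisher_exact_2x2(tp, fp, 20 - tp, 20 - fp))
        assert np.median(min_ps) < np.median(fixed_ps)
        assert np.mean(min_ps) < np.mean(fixed_ps)

    def test_single_distinct_value_rejected(self):
        with pytest.raises(ParameterError):
            optimal_dichotomization([5, 5, 5, 5], [0, 1, 0, 1])


class TestPredictiveScores:
    @pytest.mark.parametrize(
        "tt,expected",
        [
            # reconstructed operating points of two reported predictors
            ((18, 26, 0, 6), (100, 19, 41, 100)),
            ((12, 11, 0, 5), (100, 31, 52, 100)),
        ],
    )
    def test_reported_rows(self, tt, expected):
        s = predictive_scores(*tt)
        got = tuple(round(s[k]) for k in ("sensitivity", "specificity", "ppv", "npv"))
        assert got == expected

    def test_zero_denominator_nan(self):
        s = predictive_scores(0, 0, 3, 4)
        assert math.isnan(s["ppv"]) and s["npv"] == pytest.approx(100 * 4 / 7)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    def test_truth_table_identities(self, tp, fp, fn, tn):
        if tp + fn == 0 or tn + fp == 0:
            return
        s = predictive_scores(tp, fp, fn, tn)
        assert s["sensitivity"] == pytest.approx(100 * tp / (tp + fn))
        assert s["specificity"] == pytest.approx(100 * tn / (tn + fp))

    def test_rate_reconstruction_round_trips(self):
        tp, fp, fn, tn = truth_table_from_rates(44, 88, 18, 32)
        assert (tp, fp, fn, tn) == (8, 4, 10, 28)
        s = predictive_scores(tp, fp, fn, tn)
        assert round(s["ppv"]) == 67 and round(s["npv"]) == 74


class TestScreen:
    @staticmethod
    def toy_cohort(seed=0, n=40, effect=2.0):
        rng = np.random.default_rng(seed)
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        df = pd.DataFrame({
            "signal": rng.normal(0, 1, n) + effect * y,
            "noise": rng.normal(0, 1, n),
            "gated": np.where(rng.random(n) < 0.5, np.nan, rng.normal(0, 1, n)),
        })
        labels = np.where(y == 1, "malignant", "benign")
        tir = np.where(y == 1, "TIR4", "TIR2")
        return df, labels, tir

    def test_strong_signal_selected(self):
        df, labels, tir = self.toy_cohort()
        rep = screen(df, labels, tir=tir, n_boot=100, seed=1)
        assert "signal" in rep.preselected
        assert "signal" in rep.final
        r = rep.results["signal"]
        assert r.tp + r.fn == 20 and r.tn + r.fp == 20
        assert r.anova_p_diagnosis < 0.05

    def test_deterministic_given_seed(self):
        df, labels, tir = self.toy_cohort()
        r1 = screen(df, labels, tir=tir, n_boot=100, seed=3)
        r2 = screen(df, labels, tir=tir, n_boot=100, seed=3)
        assert r1.to_json() == r2.to_json()

    def test_final_subset_of_preselected(self):
        df, labels, tir = self.toy_cohort(seed=5)
        rep = screen(df, labels, tir=tir, n_boot=50, seed=2)
        assert set(rep.final) <= set(rep.preselected)
        assert set(rep.preselected) <= set(df.columns) - set(rep.not_evaluable)

    def test_pure_noise_rarely_final(self):
        # a null feature should not be a reliable final predictor; the
        # preselection rate under the null is recorded, not pinned
        pre, fin = 0, 0
        n_runs = 40
        for s in range(n_runs):
            df, labels, tir = self.toy_cohort(seed=100 + s)
            rep = screen(df[["noise"]], labels, tir=tir, n_boot=20, seed=s)
            pre += "noise" in rep.preselected
            fin += "noise" in rep.final
        assert pre / n_runs < 0.8
        assert fin / n_runs < 0.5

    def test_all_nan_feature_not_evaluable(self):
        df, labels, tir = self.toy_cohort()
        df["empty"] = np.nan
        rep = screen(df, labels, tir=tir, n_boot=20, seed=0)
        assert "empty" in rep.not_evaluable

    def test_average_scores_over_final_set(self):
        df, labels, tir = self.toy_cohort(seed=7, effect=3.0)
        rep = screen(df, labels, tir=tir, n_boot=50, seed=0)
        assert rep.final  # the strong signal must make it
        ppvs = [round(rep.results[n].ppv) for n in rep.final]
        assert rep.average_ppv == pytest.approx(np.mean(ppvs))
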
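"""ROC/Youden, classification metrics, odds ratios, group tests, Spearman
and logistic diagnostics — each checked against an independent oracle."""

import itertools
import math

import numpy as np
import pytest

from hrvidh.evaluation import (ContingencyTable2x2, classification_metrics,
                               f1_score, group_compare, logistic_diagnostics,
                               odds_ratio_ci, roc_auroc, spearman_rho)
from hrvidh.index import LogisticIndexModel, fit_logistic


def auroc_bruteforce(scores, labels):
    """Concordant-pair fraction (ties half) — exhaustive enumeration."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    conc = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return conc / (len(pos) * len(neg))


def fisher_bruteforce(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def hyper(k):
        return (math.comb(r1, k) * math.comb(r2, c1 - k)) / math.comb(n, c1)

    p_obs = hyper(a)
    return sum(hyper(k) for k in range(max(0, c1 - r2), min(r1, c1) + 1)
               if hyper(k) <= p_obs * (1 + 1e-9))


def spearman_bruteforce(x, y):
    """Pearson correlation of mid-ranks computed by explicit sorting."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx)
                    * sum((b - my) ** 2 for b in ry))
    return num / den


class TestROC:
    def test_perfect_separation(self):
        r = roc_auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert r.auroc == 1.0
        assert r.youden_index == pytest.approx(1.0)

    def test_all_ties_give_half(self):
        assert roc_auroc([0.5] * 6, [1, 1, 1, 0, 0, 0]).auroc == 0.5

    def test_matches_bruteforce_on_random_small_instances(self):
        rng = np.random.default_rng(20)
        for _ in range(300):
            n = int(rng.integers(3, 13))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            scores = rng.integers(0, 5, n).astype(float)  # force ties
            if labels.sum() in (0, n):
                continue
            r = roc_auroc(scores, labels)
            assert r.auroc == pytest.approx(
                auroc_bruteforce(scores, labels), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(21)
        scores = rng.normal(size=200)
        labels = (rng.random(200) < 0.4).astype(int)
        assert roc_auroc(scores, labels).auroc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_youden_cutoff_is_observed_and_reproducible(self):
        rng = np.random.default_rng(22)
        scores = np.round(rng.normal(0.5, 0.2, 80), 2)
        labels = (rng.random(80) < scores.clip(0, 1)).astype(int)
        r = roc_auroc(scores, labels)
        assert r.youden_cutoff in scores
        pred = scores >= r.youden_cutoff
        sens = np.sum(pred & (labels == 1)) / labels.sum()
        spec = np.sum(~pred & (labels == 0)) / (len(labels) - labels.sum())
        assert sens + spec - 1 == pytest.approx(r.youden_index)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auroc([0.1, 0.2], [1, 1])


class TestClassificationMetrics:
    def test_f1_from_printed_precision_recall(self):
        assert round(f1_score(0.707, 0.784), 3) == 0.744

    def test_confusion_counts_sensitivity_specificity(self):
        # TP 27, FN 10, TN 24, FP 9 -> 73.0 % / 72.7 %
        truth = [1] * 37 + [0] * 33
        pred = [1] * 27 + [0] * 10 + [0] * 24 + [1] * 9
        m = classification_metrics(pred, truth)
        assert round(m.recall, 3) == 0.730
        assert round(m.specificity, 3) == 0.727
        assert m.f1 == pytest.approx(f1_score(m.precision, m.recall))

    def test_identity_prediction_is_perfect(self):
        truth = [1, 0, 1, 1, 0]
        m = classification_metrics(truth, truth)
        assert m.accuracy == m.recall == m.precision == m.f1 == 1.0

    def test_no_predicted_positives_reports_missing(self):
        m = classification_metrics([0, 0, 0], [1, 0, 1])
        assert m.precision is None and m.f1 is None


class TestOddsRatio:
    def test_dm_table(self):
        orv, (lo, hi) = odds_ratio_ci(ContingencyTable2x2(30, 15, 7, 18))
        assert orv == pytest.approx(5.143, abs=5e-4)
        assert lo == pytest.approx(1.763, abs=1e-3)
        assert hi == pytest.approx(15.003, abs=1e-2)

    def test_female_table(self):
        orv, (lo, hi) = odds_ratio_ci(ContingencyTable2x2(23, 12, 14, 21))
        assert orv == pytest.approx(2.875, abs=5e-4)
        assert lo == pytest.approx(1.088, abs=1e-3)
        assert hi == pytest.approx(7.598, abs=1e-2)

    def test_null_table_symmetric_on_log_scale(self):
        orv, (lo, hi) = odds_ratio_ci(ContingencyTable2x2(1, 1, 1, 1))
        assert orv == 1.0
        assert math.log(hi) == pytest.approx(-math.log(lo))

    def test_swap_invariances(self):
        t = ContingencyTable2x2(12, 5, 7, 20)
        orv, _ = odds_ratio_ci(t)
        both_swapped, _ = odds_ratio_ci(ContingencyTable2x2(20, 7, 5, 12))
        rows_swapped, _ = odds_ratio_ci(ContingencyTable2x2(7, 20, 12, 5))
        assert both_swapped == pytest.approx(orv)
        assert rows_swapped == pytest.approx(1 / orv)

    def test_ci_contains_estimate_and_shrinks_with_counts(self):
        orv, (lo, hi) = odds_ratio_ci(ContingencyTable2x2(12, 5, 7, 20))
        assert lo < orv < hi
        _, (lo10, hi10) = odds_ratio_ci(ContingencyTable2x2(120, 50, 70, 200))
        assert (math.log(hi10) - math.log(lo10)) < (math.log(hi) - math.log(lo))

    def test_zero_cell_errors_unless_haldane(self):
        with pytest.raises(ValueError):
            odds_ratio_ci(ContingencyTable2x2(0, 5, 7, 20))
        orv, _ = odds_ratio_ci(ContingencyTable2x2(0, 5, 7, 20), haldane=True)
        assert orv > 0


class TestGroupCompare:
    def test_identical_groups_t(self):
        v = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        g = np.array([0, 0, 0, 1, 1, 1])
        t, p, name = group_compare(v, g)
        assert name == "t" and t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_degenerate_constant_groups(self):
        v = np.array([2.0, 2.0, 2.0, 2.0])
        t, p, _ = group_compare(v, np.array([0, 0, 1, 1]))
        assert t == 0.0 and p == 1.0

    def test_fisher_matches_enumeration(self):
        # forced Fisher on a table whose expected cells sit exactly at 5
        stat, p, name = group_compare(
            None, table=ContingencyTable2x2(1, 9, 11, 3), method="fisher")
        assert name == "fisher"
        assert p == pytest.approx(fisher_bruteforce(1, 9, 11, 3), abs=1e-9)

    def test_auto_fallback_uses_fisher_on_sparse_table(self):
        _, p, name = group_compare(None, table=ContingencyTable2x2(1, 2, 3, 20))
        assert name == "fisher"
        assert p == pytest.approx(fisher_bruteforce(1, 2, 3, 20), abs=1e-9)

    def test_chi_square_on_dm_counts_is_significant(self):
        stat, p, name = group_compare(
            None, table=ContingencyTable2x2(30, 15, 7, 18))
        assert name == "chi2"
        assert p < 0.05

    def test_pooled_t_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(23)
        x, y = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        v = np.concatenate([x, y])
        g = np.array([0] * 30 + [1] * 25)
        t, p, _ = group_compare(v, g)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestSpearman:
    def test_identity_and_reversal(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0]
        assert spearman_rho(x, x) == pytest.approx(1.0)
        assert spearman_rho(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_tied_example_matches_bruteforce(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0]
        y = [2.0, 1.0, 3.0, 3.0, 3.0]
        assert spearman_rho(x, y) == pytest.approx(
            spearman_bruteforce(x, y), abs=1e-12)

    def test_random_tied_data_matches_bruteforce(self):
        rng = np.random.default_rng(24)
        for _ in range(50):
            n = int(rng.integers(3, 12))
            x = rng.integers(0, 4, n).astype(float)
            y = rng.integers(0, 4, n).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            assert spearman_rho(x, y) == pytest.approx(
                spearman_bruteforce(x, y), abs=1e-12)

    def test_constant_vector_reported_missing(self):
        assert spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]) is None


class TestLogisticDiagnostics:
    def test_null_model_has_zero_nagelkerke(self):
        rng = np.random.default_rng(25)
        X = rng.normal(size=(200, 2))
        y = (rng.random(200) < 0.3).astype(int)
        null = LogisticIndexModel(
            intercept=math.log(y.mean() / (1 - y.mean())),
            coefficients={"x0": 0.0, "x1": 0.0})
        d = logistic_diagnostics(null, X, y)
        assert d["nagelkerke_r2"] == pytest.approx(0.0, abs=1e-9)

    def test_near_perfect_model_approaches_one(self):
        rng = np.random.default_rng(26)
        x = np.concatenate([rng.normal(-2, 0.3, 100), rng.normal(2, 0.3, 100)])
        y = (x > 0).astype(int)
        sharp = LogisticIndexModel(intercept=0.0, coefficients={"x0": 8.0})
        d = logistic_diagnostics(sharp, x[:, None], y)
        assert d["nagelkerke_r2"] > 0.95

    def test_too_few_risk_groups_reported_missing(self):
        X = np.zeros((50, 1))                  # constant risk -> 1 group
        y = np.array([0, 1] * 25)
        m = LogisticIndexModel(intercept=0.0, coefficients={"x0": 1.0})
        d = logistic_diagnostics(m, X, y)
        assert d["hl_p"] is None and d["reason"]

    def test_well_specified_fit_is_calibrated(self):
        rng = np.random.default_rng(27)
        X = rng.normal(size=(2000, 2))
        eta = -0.3 + 0.8 * X[:, 0] - 0.5 * X[:, 1]
        y = (rng.random(2000) < 1 / (1 + np.exp(-eta))).astype(int)
        m = fit_logistic(X, y)
        d = logistic_diagnostics(m, X, y)
        assert d["hl_p"] > 0.01                # no gross miscalibration
        assert d["n_groups"] == 10
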
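import math

import numpy as np
import pytest
from scipy import stats
from sklearn.base import clone
from sklearn.metrics import roc_auc_score

from mirdx.diagnostics import (ConfusionTable, CutoffClassifier,
                               DiagnosticsError, auc_ci, confusion_at,
                               diagnostic_metrics, evaluate_scores,
                               optimal_cutoff, roc_curve)
from mirdx.rank_tests import mann_whitney


def brute_force_youden(scores, labels):
    """Scan every candidate threshold (all midpoints + extremes) for the
    maximal J = sens + spec - 1."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    uniq = np.unique(s)
    candidates = np.r_[uniq.min() - 1, (uniq[:-1] + uniq[1:]) / 2, uniq,
                       uniq.max() + 1]
    best = -np.inf
    for c in candidates:
        pred = s >= c
        sens = (pred & (y == 1)).sum() / (y == 1).sum()
        spec = (~pred & (y == 0)).sum() / (y == 0).sum()
        best = max(best, sens + spec - 1)
    return best


class TestRocCurve:
    def test_perfect_separation(self):
        curve = roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert curve.auc == 1.0

    def test_null_scores_near_half(self, rng):
        s = rng.normal(0, 1, 2000)
        y = rng.integers(0, 2, 2000)
        assert roc_curve(s, y).auc == pytest.approx(0.5, abs=0.05)

    def test_curve_runs_from_origin_to_one_one(self, rng):
        s = rng.normal(0, 1, 50)
        y = rng.integers(0, 2, 50)
        if len(set(y)) < 2:
            y[0], y[1] = 0, 1
        c = roc_curve(s, y)
        assert (c.tpr[0], c.fpr[0]) == (0.0, 0.0)
        assert (c.tpr[-1], c.fpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(c.tpr) >= 0) and np.all(np.diff(c.fpr) >= 0)

    @pytest.mark.parametrize("with_ties", [False, True])
    def test_auc_equals_mann_whitney_u(self, with_ties, rng):
        """Cross-module identity: AUC == U/(n_pos*n_neg), ties counted 1/2."""
        for _ in range(200):
            n1, n0 = rng.integers(3, 15, 2)
            x = rng.normal(1, 1, n1)
            y0 = rng.normal(0, 1, n0)
            if with_ties:
                x, y0 = np.round(x), np.round(y0)
            scores = np.r_[y0, x]
            labels = np.r_[np.zeros(n0), np.ones(n1)].astype(int)
            u = stats.mannwhitneyu(x, y0, alternative="two-sided").statistic
            assert roc_curve(scores, labels).auc == pytest.approx(
                u / (n1 * n0), abs=1e-12)

    def test_matches_sklearn(self, rng):
        s = rng.normal(0, 1, 300)
        y = rng.integers(0, 2, 300)
        assert roc_curve(s, y).auc == pytest.approx(roc_auc_score(y, s),
                                                    abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        s = rng.normal(0, 1, 100)
        y = rng.integers(0, 2, 100)
        a = roc_curve(s, y).auc
        assert roc_curve(np.exp(s), y).auc == pytest.approx(a, abs=1e-12)
        assert roc_curve(5 * s - 3, y).auc == pytest.approx(a, abs=1e-12)

    def test_label_swap_maps_auc_to_complement(self, rng):
        s = rng.normal(0, 1, 100)
        y = rng.integers(0, 2, 100)
        assert roc_curve(s, 1 - y).auc == pytest.approx(
            1 - roc_curve(s, y).auc, abs=1e-12)

    def test_one_class_error(self):
        with pytest.raises(DiagnosticsError, match="both classes"):
            roc_curve([1, 2, 3], [1, 1, 1])


class TestAucCi:
    def test_hanley_mcneil_matches_hand_formula(self):
        scores = np.array([1, 2, 3, 4, 5, 6, 2.5, 3.5, 5.5, 7.0])
        labels = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        curve = roc_curve(scores, labels)
        a = curve.auc
        q1, q2 = a / (2 - a), 2 * a * a / (1 + a)
        se = math.sqrt((a * (1 - a) + 4 * (q1 - a * a) + 4 * (q2 - a * a)) / 25)
        lo, hi = auc_ci(curve, "hanley_mcneil")
        z = stats.norm.ppf(0.975)
        assert lo == pytest.approx(max(0, a - z * se), abs=1e-12)
        assert hi == pytest.approx(min(1, a + z * se), abs=1e-12)

    def test_symmetric_about_half_for_null_auc(self, rng):
        s = np.r_[np.arange(50), np.arange(50) + 0.5]
        y = np.r_[np.zeros(50), np.ones(50)].astype(int)
        curve = roc_curve(s, y)
        lo, hi = auc_ci(curve)
        assert (curve.auc - lo) == pytest.approx(hi - curve.auc, abs=1e-9)

    def test_delong_coverage_near_nominal(self):
        """DeLong CI covers the true binormal AUC in >=93% of simulations."""
        rng = np.random.default_rng(2024)
        d = 1.2
        true_auc = stats.norm.cdf(d / math.sqrt(2))
        covered = 0
        n_sim = 500
        for _ in range(n_sim):
            s = np.r_[rng.normal(0, 1, 40), rng.normal(d, 1, 40)]
            y = np.r_[np.zeros(40), np.ones(40)].astype(int)
            curve = roc_curve(s, y)
            lo, hi = auc_ci(curve, "delong", scores=s, labels=y)
            covered += lo <= true_auc <= hi
        assert covered / n_sim >= 0.93

    def test_degenerate_tiny_n_warns_and_clips(self):
        curve = roc_curve([1, 2, 9, 10], [0, 0, 1, 1])
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = auc_ci(curve)
        assert 0.0 <= lo <= hi <= 1.0


class TestOptimalCutoff:
    def test_four_point_toy(self):
        curve = roc_curve([1, 2, 3, 4], [0, 0, 1, 1])
        cutoff, sens, spec = optimal_cutoff(curve)
        assert cutoff == pytest.approx(2.5)
        assert sens == 1.0 and spec == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_youden_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        s = np.round(rng.normal(0, 1, 40), 1)
        y = rng.integers(0, 2, 40)
        if len(set(y.tolist())) < 2:
            y[:2] = [0, 1]
        curve = roc_curve(s, y)
        cutoff, sens, spec = optimal_cutoff(curve)
        assert sens + spec - 1 == pytest.approx(brute_force_youden(s, y),
                                                abs=1e-12)
        # the reported midpoint cutoff reproduces the optimal table
        t = confusion_at(s, y, cutoff)
        sens2 = t.tp / (t.tp + t.fn)
        spec2 = t.tn / (t.tn + t.fp)
        assert sens2 + spec2 - 1 == pytest.approx(sens + spec - 1, abs=1e-12)

    def test_all_scores_identical_degenerate(self):
        curve = roc_curve([5.0] * 6, [0, 1, 0, 1, 0, 1])
        with pytest.warns(UserWarning, match="identical"):
            cutoff, sens, spec = optimal_cutoff(curve)
        assert sens + spec - 1 == pytest.approx(0.0)
        assert (sens, spec) in {(1.0, 0.0), (0.0, 1.0)}

    def test_closest_topleft_on_toy(self):
        curve = roc_curve([1, 2, 3, 4], [0, 0, 1, 1])
        cutoff, sens, spec = optimal_cutoff(curve, "closest_topleft")
        assert (sens, spec) == (1.0, 1.0)


class TestConfusionAt:
    def test_cutoff_below_min(self):
        t = confusion_at([1, 2, 3, 4], [0, 0, 1, 1], 0.5)
        assert (t.fn, t.tn) == (0, 0)

    def test_cutoff_above_max(self):
        t = confusion_at([1, 2, 3, 4], [0, 0, 1, 1], 9.0)
        assert (t.tp, t.fp) == (0, 0)

    def test_four_point_toy_at_optimum(self):
        t = confusion_at([1, 2, 3, 4], [0, 0, 1, 1], 2.5)
        assert (t.tp, t.fp, t.fn, t.tn) == (2, 0, 0, 2)


class TestDiagnosticMetrics:
    def test_validation_cohort_worked_example(self):
        """The printed predictive-value fractions: PPV 153/170 = 90.0%,
        NPV 184/195 = 94.4% (94.3% at truncating precision)."""
        rep = diagnostic_metrics(ConfusionTable(tp=153, fp=17, fn=11, tn=184))
        assert rep.ppv * 100 == pytest.approx(90.0, abs=0.05)
        assert rep.npv * 100 == pytest.approx(94.36, abs=0.05)
        assert rep.sensitivity == pytest.approx(153 / 164)
        assert rep.specificity == pytest.approx(184 / 201)

    def test_odds_ratio_arithmetic(self):
        rep = diagnostic_metrics(ConfusionTable(tp=153, fp=17, fn=11, tn=184))
        assert rep.odds_ratio == pytest.approx(153 * 184 / (17 * 11), rel=1e-12)

    def test_symmetric_table(self):
        rep = diagnostic_metrics(ConfusionTable(10, 10, 10, 10))
        for v in (rep.sensitivity, rep.specificity, rep.ppv, rep.npv):
            assert v == pytest.approx(0.5)
        assert rep.odds_ratio == pytest.approx(1.0)
        assert rep.youden_j == pytest.approx(0.0)

    def test_zero_cell_haldane_correction(self):
        rep = diagnostic_metrics(ConfusionTable(tp=10, fp=0, fn=2, tn=8))
        assert rep.odds_ratio == pytest.approx(10.5 * 8.5 / (0.5 * 2.5))
        assert rep.odds_ratio_ci[0] > 0

    def test_clopper_pearson_contains_point_estimate(self, rng):
        for _ in range(30):
            tp, fp, fn, tn = rng.integers(1, 50, 4)
            rep = diagnostic_metrics(ConfusionTable(int(tp), int(fp),
                                                    int(fn), int(tn)))
            assert rep.sensitivity_ci[0] <= rep.sensitivity <= rep.sensitivity_ci[1]
            assert rep.ppv_ci[0] <= rep.ppv <= rep.ppv_ci[1]

    def test_clopper_pearson_coverage_at_least_nominal(self):
        rng = np.random.default_rng(99)
        p, n = 0.85, 40
        covered = 0
        reps = 2000
        ks = rng.binomial(n, p, reps)
        from statsmodels.stats.proportion import proportion_confint
        lo, hi = proportion_confint(ks, n, alpha=0.05, method="beta")
        covered = np.mean((lo <= p) & (p <= hi))
        assert covered >= 0.95

    def test_wilson_flag(self):
        rep = diagnostic_metrics(ConfusionTable(30, 5, 5, 30),
                                 ci_method="wilson")
        assert rep.sensitivity_ci[0] < rep.sensitivity < rep.sensitivity_ci[1]


class TestBinormalConvergence:
    def test_empirical_auc_converges_to_phi(self):
        """Two-class Normal(0,1) vs Normal(d,1) scores: AUC -> Phi(d/sqrt 2).
        At d = 2.475 (the planted combined-score separation over its SD) the
        limit is Phi(1.75) ~ 0.96."""
        rng = np.random.default_rng(31)
        d = 2.475
        expected = stats.norm.cdf(d / math.sqrt(2))
        s = np.r_[rng.normal(0, 1, 4000), rng.normal(d, 1, 4000)]
        y = np.r_[np.zeros(4000), np.ones(4000)].astype(int)
        assert roc_curve(s, y).auc == pytest.approx(expected, abs=0.01)
        assert expected == pytest.approx(0.9599, abs=0.001)


class TestEvaluateScores:
    def test_frozen_cutoff_skips_optimization(self, rng):
        s = np.r_[rng.normal(0, 1, 50), rng.normal(2, 1, 50)]
        y = np.r_[np.zeros(50), np.ones(50)].astype(int)
        rep = evaluate_scores(s, y, cutoff=1.0)
        assert rep.cutoff == 1.0
        t = confusion_at(s, y, 1.0)
        assert rep.confusion == t

    def test_report_serializes_to_plain_json(self, rng):
        import json
        s = np.r_[rng.normal(0, 1, 30), rng.normal(2, 1, 30)]
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)
        json.dumps(evaluate_scores(s, y).as_dict())


class TestCutoffClassifier:
    def test_sklearn_contract_and_fit(self, rng):
        est = CutoffClassifier()
        assert clone(est).get_params() == est.get_params()
        s = np.r_[rng.normal(0, 1, 50), rng.normal(2.5, 1, 50)].reshape(-1, 1)
        y = np.r_[np.zeros(50), np.ones(50)].astype(int)
        est.fit(s, y)
        assert hasattr(est, "cutoff_")
        acc = (est.predict(s) == y).mean()
        assert acc > 0.8

    def test_lower_is_positive_orientation(self, rng):
        s = np.r_[rng.normal(2.5, 1, 50), rng.normal(0, 1, 50)]
        y = np.r_[np.zeros(50), np.ones(50)].astype(int)
        est = CutoffClassifier(higher_is_positive=False).fit(s, y)
        assert est.curve_.auc > 0.9
        assert (est.predict(s) == y).mean() > 0.8
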
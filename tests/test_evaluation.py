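"""Metrics, bootstrap, calibration, fairness, group tests, attribution."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stroketriage.cohort import ValidationError
from stroketriage.evaluation import (
    CalibrationCurve,
    ConfusionMatrix,
    bootstrap_ci,
    calibration_curve,
    chi2_independence,
    confusion_metrics,
    fairness_from_rates,
    fairness_report,
    feature_attribution,
    mann_whitney_u,
    population_comparison,
    quantile_bins,
    recover_matrix_from_metrics,
    roc_auc,
    shapiro_wilk,
)

#: Published per-age-bin fairness rates of an ischemic-stroke classifier
#: (selection rate, TPR, FPR as percentages over 10 quantile age bins).
AGE_BIN_RATES = [
    (100.0, 100.0, 100.0),
    (100.0, 100.0, 100.0),
    (100.0, 100.0, 100.0),
    (81.5, 74.1, 86.8),
    (13.1, 29.4, 6.8),
    (11.5, 10.3, 13.0),
    (33.3, 48.4, 20.0),
    (17.7, 16.7, 19.2),
    (14.8, 18.8, 10.3),
    (16.0, 26.7, 0.0),
]


class TestConfusionMetrics:
    def test_lvo_test_column(self):
        """The published LVO test metrics correspond to (tp=11, fp=6,
        tn=6, fn=1): precision 64.71%, recall 91.67%, specificity 50%,
        NPV 85.71%, accuracy 70.83%, F1 75.86%."""
        m = confusion_metrics(ConfusionMatrix(tp=11, fp=6, tn=6, fn=1))
        assert round(100 * m["precision"], 2) == 64.71
        assert round(100 * m["recall"], 2) == 91.67
        assert round(100 * m["specificity"], 2) == 50.00
        assert round(100 * m["npv"], 2) == 85.71
        assert round(100 * m["accuracy"], 2) == 70.83
        assert round(100 * m["f1"], 2) == 75.86

    def test_ischemic_test_column(self):
        m = confusion_metrics(ConfusionMatrix(tp=11, fp=1, tn=1, fn=1))
        assert round(100 * m["precision"], 2) == 91.67
        assert round(100 * m["recall"], 2) == 91.67
        assert round(100 * m["specificity"], 2) == 50.00
        assert round(100 * m["npv"], 2) == 50.00
        assert round(100 * m["accuracy"], 2) == 85.71

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionMatrix(tp=5, fp=0, tn=5, fn=0))
        assert all(v == 1.0 for v in m.values())

    def test_undefined_ratio_absent_not_zero(self):
        m = confusion_metrics(ConfusionMatrix(tp=0, fp=0, tn=5, fn=0))
        assert m["precision"] is None and m["recall"] is None

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            confusion_metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_closed_forms_match_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            y = rng.integers(0, 2, 40)
            p = rng.integers(0, 2, 40)
            cm = ConfusionMatrix.from_predictions(y, p)
            m = confusion_metrics(cm)
            assert m["accuracy"] == pytest.approx((y == p).mean())


class TestRecoverMatrix:
    def test_unique_lvo_matrix_recovered(self):
        cm = recover_matrix_from_metrics(
            {"precision": 64.71, "recall": 91.67, "specificity": 50.00, "npv": 85.71}
        )
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (11, 6, 6, 1)

    def test_impossible_metrics_rejected(self):
        with pytest.raises(ValidationError, match="no confusion matrix"):
            recover_matrix_from_metrics({"precision": 64.71, "recall": 91.67,
                                         "specificity": 49.0, "npv": 85.71}, max_total=25)


class TestBootstrap:
    @staticmethod
    def _accuracy(y, p):
        return float((y == p).mean())

    def test_degenerate_zero_variance(self):
        y = np.ones(30)
        point, lo, hi = bootstrap_ci(self._accuracy, y, y, n_resamples=200, seed=0)
        assert (point, lo, hi) == (1.0, 1.0, 1.0)

    def test_seeded_repeatability(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 60)
        p = rng.integers(0, 2, 60)
        a = bootstrap_ci(self._accuracy, p, y, seed=7)
        b = bootstrap_ci(self._accuracy, p, y, seed=7)
        assert a == b

    def test_width_shrinks_like_inverse_sqrt_n(self):
        """CI width on Bernoulli accuracy scales ~ 1/sqrt(n)."""
        rng = np.random.default_rng(2)
        widths = {}
        for n in (50, 200, 800):
            y = rng.integers(0, 2, n)
            p = np.where(rng.random(n) < 0.7, y, 1 - y)  # 70% accurate
            _, lo, hi = bootstrap_ci(self._accuracy, p, y, n_resamples=500, seed=3)
            widths[n] = hi - lo
        assert widths[200] < widths[50] and widths[800] < widths[200]
        assert widths[50] / widths[800] == pytest.approx(np.sqrt(800 / 50), rel=0.5)

    def test_point_inside_interval(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 100)
        p = np.where(rng.random(100) < 0.8, y, 1 - y)
        point, lo, hi = bootstrap_ci(self._accuracy, p, y, seed=4)
        assert lo <= point <= hi


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(4)
        scores = rng.random(10_000)
        labels = rng.integers(0, 2, 10_000)
        assert abs(roc_auc(scores, labels) - 0.5) < 0.02

    def test_all_tied_exactly_half(self):
        assert roc_auc(np.full(20, 0.3), [0, 1] * 10) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_equals_normalized_u_statistic(self):
        """Dual route: AUC equals the Mann–Whitney U statistic of the
        positive-class scores normalized by n_pos * n_neg."""
        rng = np.random.default_rng(5)
        scores = np.round(rng.random(200), 2)  # force ties
        labels = rng.integers(0, 2, 200)
        pos, neg = scores[labels == 1], scores[labels == 0]
        u = mann_whitney_u(pos, neg).statistic
        assert roc_auc(scores, labels) == pytest.approx(u / (len(pos) * len(neg)))


class TestCalibration:
    def test_calibrated_simulation_max_deviation(self):
        rng = np.random.default_rng(6)
        probs = rng.random(20_000)
        labels = (rng.random(20_000) < probs).astype(int)
        curve = calibration_curve(probs, labels)
        assert curve.max_deviation < 0.03

    def test_single_bin_degenerate(self):
        curve = calibration_curve(np.full(10, 0.7), np.ones(10))
        assert len(curve.bins) == 1
        lower, upper, mean_pred, frac_pos, count = curve.bins[0]
        assert frac_pos == 1.0 and lower <= mean_pred <= upper

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(7)
        probs = rng.random(500)
        curve = calibration_curve(probs, rng.integers(0, 2, 500))
        assert sum(b[4] for b in curve.bins) == 500

    def test_mean_predicted_within_bin(self):
        rng = np.random.default_rng(8)
        probs = rng.random(300)
        for lo, hi, mean_pred, _, _ in calibration_curve(probs, rng.integers(0, 2, 300)).bins:
            assert lo <= mean_pred <= hi


class TestQuantileBins:
    def test_uniform_grid_equal_bins(self):
        codes = quantile_bins(np.arange(1, 101), 10)
        assert np.bincount(codes).tolist() == [10] * 10

    def test_constant_values_single_bin_warns(self):
        with pytest.warns(UserWarning, match="distinct quantile bins"):
            codes = quantile_bins(np.ones(20), 10)
        assert len(np.unique(codes)) == 1

    def test_assignment_monotone(self):
        rng = np.random.default_rng(9)
        v = rng.normal(size=200)
        codes = quantile_bins(v, 10)
        order = np.argsort(v)
        assert np.all(np.diff(codes[order]) >= 0)


class TestFairness:
    def test_published_age_bin_rates_reproduced(self):
        """From the printed per-age-bin rates: demographic parity
        difference 0.885 and equalized odds difference 1.0."""
        sel = [r[0] / 100 for r in AGE_BIN_RATES]
        tpr = [r[1] / 100 for r in AGE_BIN_RATES]
        fpr = [r[2] / 100 for r in AGE_BIN_RATES]
        dpd, eod = fairness_from_rates(sel, tpr, fpr)
        assert dpd == pytest.approx(0.885)
        assert eod == pytest.approx(1.0)

    def test_identical_groups_zero_disparity(self):
        pred = np.array([1, 0, 1, 0] * 10)
        lab = np.array([1, 0, 0, 1] * 10)
        grp = np.array(["a", "a", "b", "b"] * 10)
        # group a and b see identical prediction/label patterns
        rep = fairness_report(np.concatenate([pred, pred]),
                              np.concatenate([lab, lab]),
                              np.concatenate([grp, grp]))
        assert rep.dpd == pytest.approx(abs(np.mean(pred[grp == "a"]) - np.mean(pred[grp == "b"])))

    def test_symmetric_groups(self):
        pred = np.array([1, 0] * 20)
        lab = np.array([1, 0] * 20)
        grp = np.array(["a"] * 20 + ["b"] * 20)
        rep = fairness_report(pred, lab, grp)
        assert rep.dpd == 0.0 and rep.eod == 0.0

    def test_bounded_and_relabel_invariant(self):
        rng = np.random.default_rng(10)
        pred, lab = rng.integers(0, 2, 120), rng.integers(0, 2, 120)
        grp = rng.choice(list("xyz"), 120)
        a = fairness_report(pred, lab, grp)
        swapped = np.array([{"x": "z", "y": "x", "z": "y"}[g] for g in grp])
        b = fairness_report(pred, lab, swapped)
        assert 0 <= a.dpd <= 1 and 0 <= a.eod <= 1
        assert a.dpd == pytest.approx(b.dpd) and a.eod == pytest.approx(b.eod)

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            fairness_report([1, 0], [1, 0], ["a", "a"])

    def test_group_without_negatives_excluded_from_eod(self):
        pred = np.array([1, 1, 1, 0, 1, 0])
        lab = np.array([1, 1, 1, 0, 1, 0])  # group a has no negatives
        grp = np.array(["a", "a", "a", "b", "b", "b"])
        rep = fairness_report(pred, lab, grp)
        assert rep.fpr[0] is None


class TestChi2:
    def test_exact_independence(self):
        rep = chi2_independence([[50, 50], [50, 50]])
        assert rep.statistic == 0.0 and rep.p_value == 1.0

    def test_hand_computed_value(self):
        rep = chi2_independence([[10, 20], [20, 10]])
        assert rep.statistic == pytest.approx(20 / 3)
        assert rep.dof == 1

    def test_doubling_cells_doubles_statistic(self):
        a = chi2_independence([[10, 20], [20, 10]]).statistic
        b = chi2_independence([[20, 40], [40, 20]]).statistic
        assert b == pytest.approx(2 * a)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValidationError, match="marginal"):
            chi2_independence([[0, 0], [10, 20]])


class TestMannWhitney:
    def test_extreme_separation(self):
        rep = mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert rep.statistic == 0.0
        rep_rev = mann_whitney_u([10, 11, 12], [1, 2, 3])
        assert rep_rev.statistic == 9.0

    def test_identical_multisets_half(self):
        rep = mann_whitney_u([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert rep.statistic == 8.0  # n^2 / 2

    def test_small_sample_p_matches_permutation_enumeration(self):
        """Exhaustive oracle: the two-sided p for a 3-vs-3 comparison
        equals the fraction of label permutations with |U - n^2/2| at
        least as extreme."""
        x, y = [1.2, 3.4, 5.1], [2.2, 6.5, 7.9]
        rep = mann_whitney_u(x, y)
        pooled = np.array(x + y)
        u_obs = rep.statistic
        center = 9 / 2
        count = total = 0
        for combo in itertools.combinations(range(6), 3):
            xs = pooled[list(combo)]
            ys = pooled[[i for i in range(6) if i not in combo]]
            u = sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)
            total += 1
            if abs(u - center) >= abs(u_obs - center) - 1e-12:
                count += 1
        assert rep.p_value == pytest.approx(count / total)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])


def test_shapiro_wilk_delegation():
    rng = np.random.default_rng(11)
    rep = shapiro_wilk(rng.normal(size=100))
    assert rep.test == "shapiro_wilk" and rep.p_value > 0.001
    assert shapiro_wilk(rng.exponential(size=200) ** 3).p_value < 0.01


@pytest.fixture(scope="module")
def leak_model():
    from stroketriage.models import REFERENCE_MODELS, TuningConfig, tune_and_fit

    rng = np.random.default_rng(7)
    y = rng.integers(0, 2, size=80)
    X = rng.normal(size=(80, 5))
    X[:, 3] = y
    Xd = pd.DataFrame(X, columns=[f"f{i}" for i in range(5)])
    return Xd, y, tune_and_fit(Xd, y, REFERENCE_MODELS["ischemic"], TuningConfig(seed=0))


class TestAttribution:
    def test_label_copy_ranked_first(self, leak_model):
        X, y, model = leak_model
        att = feature_attribution(model, X, y, n_repeats=5, seed=0)
        assert att.iloc[0]["feature"] == "f3"

    def test_noise_importance_near_zero(self, leak_model):
        X, y, model = leak_model
        att = feature_attribution(model, X, y, n_repeats=10, seed=0)
        noise = att[att.feature != "f3"]["importance"]
        assert (noise < 0.05).all()

    def test_seeded_ranking_stable(self, leak_model):
        X, y, model = leak_model
        a = feature_attribution(model, X, y, n_repeats=5, seed=1)
        b = feature_attribution(model, X, y, n_repeats=5, seed=1)
        assert list(a.feature) == list(b.feature)

    def test_unknown_method_rejected(self, leak_model):
        X, y, model = leak_model
        with pytest.raises(ValidationError, match="method"):
            feature_attribution(model, X, y, method="gradients")


class TestPopulationComparison:
    def test_self_comparison_all_comparable(self):
        y = np.array([0, 1, 1, 0, 1])
        p = np.array([0, 1, 0, 0, 1])
        out = population_comparison({"complete": (y, p)}, {"complete": (y, p)})
        assert (out["delta_f1"] == 0).all()
        assert (out["band_f1"] == "comparable").all()

    def test_band_thresholds_at_five_points(self):
        from stroketriage.evaluation import _band

        assert _band(0.06) == "better"
        assert _band(-0.06) == "worse"
        assert _band(0.04) == "comparable"

    def test_subset_containment_counts(self):
        rng = np.random.default_rng(12)
        y = rng.integers(0, 2, 50)
        p = rng.integers(0, 2, 50)
        sub = slice(0, 30)
        out = population_comparison(
            {"bayes-ischemic": (y[sub], p[sub]), "complete": (y, p)},
            {"bayes-ischemic": (y[sub], p[sub]), "complete": (y, p)},
        )
        assert set(out["subset"]) == {"bayes-ischemic", "complete"}
        assert len(out) == 4  # two classes per subset
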
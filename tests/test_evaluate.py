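"""Evaluation suite: DeLong machinery, threshold metrics, calibration,
decision curves, Shapley attribution, nomogram."""

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import habitatbm as hb
from habitatbm.evaluate import (
    auc_delong,
    calibration_curve_points,
    decision_curve,
    delong_test,
    hosmer_lemeshow,
    nomogram_export,
    shapley_attribution,
    threshold_metrics,
    youden_threshold,
)


def brute_force_auc(scores, labels):
    """Exhaustive concordant-pair counting with 0.5 tie credit."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_documented_example(self):
        auc, _, _ = auc_delong([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        auc, var, ci = auc_delong([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0 and ci[1] == 1.0

    def test_all_ties_give_half(self):
        auc, _, _ = auc_delong([0.5] * 10, [0, 1] * 5)
        assert auc == pytest.approx(0.5)

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(0)
        for n in (8, 20, 50):
            scores = np.round(rng.uniform(size=n), 2)  # induce ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            auc, var, _ = auc_delong(scores, labels)
            assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
            assert var >= 0

    def test_ci_shrinks_with_n(self):
        rng = np.random.default_rng(1)
        widths = []
        for n in (50, 200, 800):
            scores = rng.normal(loc=rng.integers(0, 2, n).astype(float), scale=1.0)
            labels = (scores + rng.normal(0, 1, n) > 0.5).astype(int)
            _, _, (lo, hi) = auc_delong(scores, labels)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_delong([0.1, 0.2], [1, 1])


class TestDeLongTest:
    def test_identical_scores_z_zero_p_one(self):
        s = [0.1, 0.4, 0.35, 0.8]
        z, p = delong_test(s, s, [0, 0, 1, 1])
        assert z == 0.0 and p == 1.0

    def test_informative_beats_noise_with_power(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 200
            y = rng.integers(0, 2, n)
            good = y + rng.normal(0, 0.5, n)
            noise = rng.normal(0, 1, n)
            _, p = delong_test(good, noise, y)
            hits += p < 0.05
        assert hits >= 9

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            delong_test([0.1, 0.2], [0.1], [0, 1])


class TestThresholdMetrics:
    def test_printed_confusion_ratios(self):
        """TP=15, FN=2, TN=26, FP=14 -> closed-form rates."""
        scores = np.concatenate([
            np.full(15, 0.9), np.full(2, 0.1),   # positives
            np.full(26, 0.1), np.full(14, 0.9),  # negatives
        ])
        labels = np.array([1] * 17 + [0] * 40)
        m = threshold_metrics(scores, labels, threshold=0.5)
        assert m["sensitivity"] == pytest.approx(15 / 17)
        assert m["specificity"] == pytest.approx(26 / 40)
        assert m["ppv"] == pytest.approx(15 / 29)
        assert m["npv"] == pytest.approx(26 / 28)
        assert m["accuracy"] == pytest.approx((15 + 26) / 57)

    def test_perfect_scores_all_metrics_one(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = [1, 1, 0, 0]
        m = threshold_metrics(scores, labels, threshold=0.5)
        assert all(m[k] == 1.0 for k in ("sensitivity", "specificity", "ppv", "npv", "accuracy"))

    def test_all_positive_predictions(self):
        labels = np.array([1] * 3 + [0] * 7)
        scores = np.full(10, 0.9)
        m = threshold_metrics(scores, labels, threshold=0.5)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0
        assert m["ppv"] == pytest.approx(0.3)  # prevalence

    def test_youden_threshold_maximizes_j(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 100)
        s = y + rng.normal(0, 0.7, 100)
        t = youden_threshold(s, y)
        m = threshold_metrics(s, y, threshold=t)
        j_star = m["sensitivity"] + m["specificity"] - 1
        for other in np.quantile(s, [0.1, 0.3, 0.5, 0.7, 0.9]):
            mo = threshold_metrics(s, y, threshold=other)
            assert j_star >= mo["sensitivity"] + mo["specificity"] - 1 - 1e-12


class TestHosmerLemeshow:
    def test_exact_calibration_statistic_zero(self):
        # 10 groups of 10 with probabilities equal to observed group rates
        probs, labels = [], []
        for g in range(10):
            rate = (g + 1) / 12
            k = round(rate * 10)
            probs += [k / 10] * 10
            labels += [1] * k + [0] * (10 - k)
        stat, p = hosmer_lemeshow(np.array(probs), np.array(labels), groups=10)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_statistic_calibrated_under_true_probabilities(self):
        """With known (not fitted) probabilities the statistic is chi-square
        with g degrees of freedom; its p-values are uniform (KS check).  The
        g-2 correction reported by the function applies to fitted models."""
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(200):
            p = rng.uniform(0.05, 0.95, 500)
            y = rng.binomial(1, p)
            stat, _ = hosmer_lemeshow(p, y)
            pvals.append(stats.chi2.sf(stat, 10))
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow(np.full(15, 0.5), np.zeros(15), groups=10)

    def test_calibration_curve_points_shape(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=200)
        y = rng.binomial(1, p)
        pts = calibration_curve_points(p, y)
        assert len(pts) == 10 and pts["n"].sum() == 200


class TestDecisionCurve:
    def test_treat_all_limits(self):
        y = np.array([1] * 3 + [0] * 7)
        dca = decision_curve(np.full(10, 0.5), y, threshold_grid=[1e-6, 0.5])
        assert dca.iloc[0]["treat_all"] == pytest.approx(0.3, abs=1e-5)

    def test_treat_all_zero_at_half_with_half_prevalence(self):
        y = np.array([1] * 5 + [0] * 5)
        dca = decision_curve(np.full(10, 0.5), y, threshold_grid=[0.5])
        assert dca.iloc[0]["treat_all"] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_model_net_benefit_is_prevalence(self):
        y = np.array([1] * 4 + [0] * 6)
        p = np.where(y == 1, 0.999, 0.001)
        dca = decision_curve(p, y)
        assert np.allclose(dca["net_benefit"], 0.4)
        assert (dca["net_benefit"] >= dca["treat_all"] - 1e-12).all()
        assert (dca["net_benefit"] <= y.mean() + 1e-12).all()

    def test_unit_threshold_excluded(self):
        y = np.array([1, 0, 1, 0])
        dca = decision_curve([0.5] * 4, y, threshold_grid=[0.5, 1.0])
        assert len(dca) == 1


class TestShapley:
    def _linear_model(self, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.standard_normal((200, 3)), columns=list("abc"))
        y = ((X["a"] - 0.5 * X["b"] + 0.25 * X["c"]) > 0).astype(int).to_numpy()
        model = hb.train_model(X, y, hb.SignatureSpec("lin", list("abc")), "LR",
                               cv_folds=3, seed=0)
        return model, X

    def test_local_accuracy_linear(self):
        model, X = self._linear_model()
        rep = shapley_attribution(model, X.iloc[:20], X.iloc[100:])
        assert rep.local_accuracy_error() < 1e-6

    def test_local_accuracy_tree(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.standard_normal((200, 3)), columns=list("abc"))
        y = (X["a"] > 0).astype(int).to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = hb.train_model(X, y, hb.SignatureSpec("t", list("abc")),
                                   "XGBoost", seed=0, tune=False)
        rep = shapley_attribution(model, X.iloc[:20], X.iloc[100:])
        assert rep.method == "tree_exact"
        assert rep.local_accuracy_error() < 1e-5  # float32 tree contributions

    def test_linear_matches_exhaustive_coalition_enumeration(self):
        """Exact Shapley by 2^3 coalition enumeration for an additive model
        equals w_j (x_j - mean background_j)."""
        model, X = self._linear_model()
        background = X.iloc[100:150]
        rows = X.iloc[:5]
        rep = shapley_attribution(model, rows, background)
        from habitatbm.evaluate import _linear_params

        w, b = _linear_params(model.estimator)
        B = background.to_numpy()

        def value(S, x):
            """Expected margin with coalition S fixed at x."""
            mat = B.copy()
            for j in S:
                mat[:, j] = x[j]
            return (mat @ w + b).mean()

        from math import factorial

        feats = range(3)
        for i in range(5):
            x = rows.iloc[i].to_numpy()
            for j in feats:
                phi = 0.0
                others = [f for f in feats if f != j]
                for size in range(len(others) + 1):
                    for S in combinations(others, size):
                        weight = factorial(len(S)) * factorial(2 - len(S)) / factorial(3)
                        phi += weight * (value(S + (j,), x) - value(S, x))
                assert rep.values[i, j] == pytest.approx(phi, abs=1e-9)

    def test_unused_feature_zero_contribution(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"used": rng.standard_normal(300),
                          "unused": rng.standard_normal(300)})
        y = (X["used"] > 0).astype(int).to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = hb.train_model(X, y, hb.SignatureSpec("t", ["used", "unused"]),
                                   "XGBoost", seed=0, tune=False)
        rep = shapley_attribution(model, X.iloc[:30], X.iloc[100:])
        assert np.allclose(rep.values[:, 1], 0.0, atol=1e-8)

    def test_background_required(self):
        model, X = self._linear_model()
        with pytest.raises(ValueError):
            shapley_attribution(model, X.iloc[:5], X.iloc[:0])

    def test_sampled_fallback_for_nonlinear_models(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((150, 2)), columns=list("ab"))
        y = (X["a"] * X["b"] > 0).astype(int).to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = hb.train_model(X, y, hb.SignatureSpec("rf", list("ab")),
                                   "RandomForest", seed=0, tune=False)
        rep = shapley_attribution(model, X.iloc[:5], X.iloc[50:80], n_permutations=16, seed=0)
        assert rep.method == "permutation_sampled"
        assert rep.values.shape == (5, 2)
        assert np.isfinite(rep.values).all()


class TestNomogram:
    def test_round_trip_probability(self):
        coefs = {"a": 1.2, "b": -0.7}
        nomo = nomogram_export(coefs, {"a": (0, 10), "b": (-5, 5)}, intercept=-1.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            row = {"a": rng.uniform(0, 10), "b": rng.uniform(-5, 5)}
            eta = 1.2 * row["a"] - 0.7 * row["b"] - 1.0
            expected = 1 / (1 + np.exp(-eta))
            assert nomo.probability(row) == pytest.approx(expected, abs=1e-6)

    def test_single_predictor_points_proportional(self):
        nomo = nomogram_export({"a": 2.0}, {"a": (0, 1)}, intercept=0.0)
        p1 = nomo.points({"a": 0.25})
        p2 = nomo.points({"a": 0.5})
        assert p2 == pytest.approx(2 * p1)
        assert nomo.points({"a": 1.0}) == pytest.approx(100.0)

    def test_two_to_one_coefficients_scale_100_to_50(self):
        nomo = nomogram_export({"a": 2.0, "b": 1.0}, {"a": (0, 1), "b": (0, 1)},
                               intercept=0.0)
        t = nomo.table()
        assert t.loc["a", "max_points"] == pytest.approx(100.0)
        assert t.loc["b", "max_points"] == pytest.approx(50.0)

    def test_nonlinear_model_rejected(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.standard_normal((100, 2)), columns=list("ab"))
        y = (X["a"] > 0).astype(int).to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = hb.train_model(X, y, hb.SignatureSpec("rf", list("ab")),
                                   "RandomForest", seed=0, tune=False)
        with pytest.raises(ValueError, match="logistic"):
            nomogram_export(model, {"a": (0, 1), "b": (0, 1)})

    def test_fitted_lr_round_trip(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((200, 2)), columns=list("ab"))
        y = (X["a"] - X["b"] > 0).astype(int).to_numpy()
        model = hb.train_model(X, y, hb.SignatureSpec("lr", list("ab")), "LR",
                               cv_folds=3, seed=0)
        ranges = {c: (X[c].min(), X[c].max()) for c in X.columns}
        nomo = nomogram_export(model, ranges)
        for i in range(10):
            expected = hb.predict(model, X.iloc[[i]])[0]
            assert nomo.probability(X.iloc[i]) == pytest.approx(expected, abs=1e-6)


class TestAUCProperties:
    from hypothesis import given, settings, strategies as st

    # a discrete score grid keeps ties exact under the transform (nearly
    # equal floats could otherwise collapse to ties and change the AUC)
    @given(st.lists(st.integers(min_value=0, max_value=1000),
                    min_size=4, max_size=30))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_invariant_under_monotone_score_transform(self, scores):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, len(scores))
        if labels.min() == labels.max():
            labels[0] ^= 1
        s = np.asarray(scores) / 1000.0
        a1, _, _ = auc_delong(s, labels)
        a2, _, _ = auc_delong(np.exp(3 * s), labels)  # strictly increasing map
        assert a1 == pytest.approx(a2, abs=1e-12)
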
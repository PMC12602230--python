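"""Five-stage feature-selection cascade."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import habitatbm as hb
from habitatbm.selection import (
    SelectionReport,
    correlation_prune,
    lasso_select,
    mrmr_select,
    recursive_elimination,
    run_selection_cascade,
    significance_filter,
)


def toy_table(n=40, p=10, seed=0, signal_cols=()):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = rng.integers(0, 2, n)
    for c in signal_cols:
        X[:, c] += 2.0 * y
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(p)]), y


class TestSignificanceFilter:
    def test_constant_feature_dropped(self):
        df, y = toy_table()
        df["const"] = 1.0
        rep = SelectionReport()
        kept = significance_filter(df, y, report=rep)
        assert "const" not in kept
        assert rep.p_values["const"] == 1.0

    def test_perfectly_separated_feature_retained(self):
        """Non-overlapping classes at n=20/20: exact U-test p < 1e-6."""
        rng = np.random.default_rng(0)
        y = np.array([0] * 20 + [1] * 20)
        x = np.concatenate([rng.uniform(0, 1, 20), rng.uniform(2, 3, 20)])
        p_exact = stats.mannwhitneyu(x[y == 0], x[y == 1], alternative="two-sided").pvalue
        assert p_exact < 1e-6
        df = pd.DataFrame({"sep": x})
        assert significance_filter(df, y) == ["sep"]

    def test_tiny_class_rejected(self):
        df, _ = toy_table(n=5)
        with pytest.raises(ValueError):
            significance_filter(df, np.array([0, 0, 0, 0, 1]))


class TestCorrelationPrune:
    def test_duplicate_column_one_survivor(self):
        df, _ = toy_table()
        df["dup"] = df["f0"]
        kept = correlation_prune(df, threshold=0.9)
        assert ("f0" in kept) != ("dup" in kept)

    def test_orthogonal_features_all_survive(self):
        rng = np.random.default_rng(1)
        q, _ = np.linalg.qr(rng.standard_normal((50, 5)))
        df = pd.DataFrame(q, columns=list("abcde"))
        assert correlation_prune(df, threshold=0.9) == list("abcde")

    def test_victim_is_larger_mean_absolute_correlation(self):
        """r(1,2) ~ 0.95, r(1,3) ~ 0.3, r(2,3) ~ 0.15: feature 1 has the
        larger mean |r| and is dropped; 2 and 3 survive."""
        target = np.array([[1.0, 0.95, 0.30], [0.95, 1.0, 0.15], [0.30, 0.15, 1.0]])
        L = np.linalg.cholesky(target)
        rng = np.random.default_rng(2)
        X = rng.standard_normal((5000, 3)) @ L.T
        df = pd.DataFrame(X, columns=["f1", "f2", "f3"])
        kept = correlation_prune(df, threshold=0.9)
        assert kept == ["f2", "f3"]

    def test_result_has_no_pair_above_threshold(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal((60, 4))
        X = np.column_stack([base, base + 0.05 * rng.standard_normal((60, 4))])
        df = pd.DataFrame(X, columns=[f"g{i}" for i in range(8)])
        kept = correlation_prune(df, threshold=0.9)
        corr = df[kept].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0)
        assert corr.max() < 0.9


class TestRFE:
    def test_predictive_feature_survives(self):
        df, y = toy_table(n=80, signal_cols=(0,))
        kept = recursive_elimination(df, y, target_n=1, seed=0)
        assert kept == ["f0"]

    def test_identity_when_target_reaches_count(self):
        df, y = toy_table()
        with pytest.warns(UserWarning):
            kept = recursive_elimination(df, y, target_n=10)
        assert kept == list(df.columns)

    def test_zero_step_rejected(self):
        df, y = toy_table()
        with pytest.raises(ValueError):
            recursive_elimination(df, y, target_n=2, step=0)


class TestMRMR:
    def test_first_pick_is_max_relevance(self):
        df, y = toy_table(n=100, signal_cols=(3,))
        order = mrmr_select(df, y, target_n=3)
        assert order[0] == "f3"

    def test_duplicate_of_top_not_second(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 100)
        df = pd.DataFrame(rng.standard_normal((100, 6)),
                          columns=[f"f{i}" for i in range(6)])
        df["f0"] += 2.0 * y       # dominant feature
        df["f5"] += 1.0 * y       # weaker independent signal
        df["dup0"] = df["f0"] + 1e-9
        order = mrmr_select(df, y, target_n=3)
        assert order[0] in ("f0", "dup0")
        assert order[1] not in ("f0", "dup0")

    def test_greedy_order_matches_brute_force(self):
        """Five-feature toy: full greedy order equals exhaustive evaluation
        of the (normalized F relevance - mean |r| redundancy) criterion."""
        from sklearn.feature_selection import f_classif

        df, y = toy_table(n=60, p=5, seed=4, signal_cols=(1, 4))
        rel = f_classif(df.to_numpy(), y)[0]
        rel = rel / rel.max()
        corr = np.abs(np.corrcoef(df.to_numpy(), rowvar=False))
        cols = list(df.columns)
        selected = [int(np.argmax(rel))]
        while len(selected) < 5:
            best, best_score = None, -np.inf
            for i in range(5):
                if i in selected:
                    continue
                score = rel[i] - corr[i, selected].mean()
                if score > best_score:
                    best, best_score = i, score
            selected.append(best)
        expected = [cols[i] for i in selected]
        assert mrmr_select(df, y, target_n=5) == expected


class TestLasso:
    def test_infinite_penalty_no_survivors(self):
        df, y = toy_table(n=60, signal_cols=(0,))
        rep = SelectionReport()
        kept, weights = lasso_select(df, y, c_grid=np.array([1e-8]), report=rep)
        assert kept == [] and weights == {}
        assert rep.no_signal

    def test_survivors_nested_in_penalty(self):
        df, y = toy_table(n=100, signal_cols=(0, 1))
        strong, _ = lasso_select(df, y, c_grid=np.array([0.05]))
        weak, _ = lasso_select(df, y, c_grid=np.array([10.0]))
        assert set(strong) <= set(weak)

    def test_planted_predictor_recovery(self):
        """3 true predictors among 50 at n=200: recovered in >= 8/10 seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((200, 50))
            eta = 1.5 * X[:, 0] + 1.2 * X[:, 1] - 1.3 * X[:, 2]
            y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
            df = pd.DataFrame(X, columns=[f"f{i}" for i in range(50)])
            kept, _ = lasso_select(df, y, cv_folds=10, seed=seed)
            if {"f0", "f1", "f2"} <= set(kept):
                hits += 1
        assert hits >= 8


class TestCascade:
    def test_stage_nesting(self):
        df, y = toy_table(n=80, p=30, signal_cols=(0, 1, 2))
        rep = run_selection_cascade(df, y, rfe_target=15, mrmr_target=8, cv_folds=5, seed=0)
        stages = list(rep.stages.values())
        for earlier, later in zip(stages, stages[1:]):
            assert set(later) <= set(earlier)
        assert rep.selected

    def test_leakage_hygiene_selection_independent_of_validation(self):
        df, y = toy_table(n=120, p=20, signal_cols=(0,))
        train = df.iloc[:80]
        rep1 = run_selection_cascade(train, y[:80], rfe_target=10, mrmr_target=5, cv_folds=5, seed=0)
        # mutate "validation" rows: selection must not change
        df2 = df.copy()
        df2.iloc[80:] = 999.0
        rep2 = run_selection_cascade(df2.iloc[:80], y[:80], rfe_target=10, mrmr_target=5, cv_folds=5, seed=0)
        assert rep1.selected == rep2.selected

    def test_type_one_error_near_alpha(self):
        """Null features: retained fraction ~ alpha (checked loosely here;
        the calibrated 2,000-feature check lives in the acceptance suite)."""
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 400))
        y = rng.integers(0, 2, 60)
        df = pd.DataFrame(X, columns=[f"n{i}" for i in range(400)])
        kept = significance_filter(df, y, alpha=0.05)
        assert 0.01 <= len(kept) / 400 <= 0.10
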
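"""Five-stage feature-selection cascade.

Stages, applied to training rows only and strictly nested:

1. significance filter — per feature, Shapiro-Wilk normality per class
   decides t-test vs Mann-Whitney U; keep p < alpha.
2. correlation pruning — greedy removal until all pairwise |Pearson r| are
   below threshold; within an offending pair the feature with the larger
   mean absolute correlation to all others is dropped.
3. recursive feature elimination with a seeded linear estimator.
4. mRMR (difference variant: F-statistic relevance minus mean |r| redundancy).
5. logistic LASSO over a C grid with stratified CV; survivors are the
   nonzero coefficients and define the Rad-score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.feature_selection import RFE, f_classif
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

__all__ = [
    "SelectionReport",
    "significance_filter",
    "correlation_prune",
    "recursive_elimination",
    "mrmr_select",
    "lasso_select",
    "run_selection_cascade",
]


@dataclass
class SelectionReport:
    """Per-stage survivors and diagnostics of the cascade."""

    stages: dict[str, list[str]] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    correlation_dropped: list[str] = field(default_factory=list)
    mrmr_scores: dict[str, float] = field(default_factory=dict)
    lasso_c_grid: list[float] = field(default_factory=list)
    chosen_c: float = float("nan")
    rad_score_weights: dict[str, float] = field(default_factory=dict)
    rad_score_intercept: float = float("nan")
    no_signal: bool = False

    @property
    def selected(self) -> list[str]:
        if not self.stages:
            return []
        return list(self.stages.values())[-1]

    def record(self, stage: str, survivors: list[str]) -> None:
        if self.stages:
            prev = set(list(self.stages.values())[-1])
            assert set(survivors) <= prev, "stage survivors must be nested"
        self.stages[stage] = list(survivors)


def significance_filter(
    table: pd.DataFrame, y: np.ndarray, alpha: float = 0.05,
    report: SelectionReport | None = None,
) -> list[str]:
    """Keep features differing between classes at p < alpha.

    Normality is assessed per class with Shapiro-Wilk (alpha 0.05); features
    normal in both classes use Welch's t-test, others Mann-Whitney U.
    """
    y = np.asarray(y)
    g0 = table.loc[y == 0]
    g1 = table.loc[y == 1]
    if len(g0) < 3 or len(g1) < 3:
        raise ValueError("each class needs at least 3 observations")
    survivors = []
    for col in table.columns:
        a = g0[col].to_numpy(dtype=float)
        b = g1[col].to_numpy(dtype=float)
        if np.var(a) == 0 and np.var(b) == 0:
            p = 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                normal = (
                    np.var(a) > 0 and np.var(b) > 0
                    and stats.shapiro(a).pvalue > 0.05
                    and stats.shapiro(b).pvalue > 0.05
                )
                if normal:
                    p = stats.ttest_ind(a, b, equal_var=False).pvalue
                else:
                    p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        if report is not None:
            report.p_values[col] = float(p)
        if p < alpha:
            survivors.append(col)
    return survivors


def correlation_prune(
    table: pd.DataFrame, threshold: float = 0.9,
    report: SelectionReport | None = None,
) -> list[str]:
    """Greedy pruning until all pairwise |Pearson r| < threshold.

    Zero-variance features are dropped first; among a correlated pair the
    feature with the larger mean absolute correlation to all remaining
    features is dropped.
    """
    cols = list(table.columns)
    if len(cols) < 2:
        return cols
    variances = table.var(ddof=0)
    dead = [c for c in cols if variances[c] <= 0]
    if dead and report is not None:
        report.correlation_dropped.extend(dead)
    cols = [c for c in cols if c not in dead]
    corr = table[cols].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    active = np.ones(len(cols), dtype=bool)
    while True:
        sub = corr[np.ix_(active, active)]
        if sub.size == 0 or sub.max() < threshold:
            break
        act_idx = np.flatnonzero(active)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        a, b = act_idx[i], act_idx[j]
        mean_a = corr[a, active].mean()
        mean_b = corr[b, active].mean()
        victim = a if mean_a >= mean_b else b
        active[victim] = False
        if report is not None:
            report.correlation_dropped.append(cols[victim])
    return [c for c, keep in zip(cols, active) if keep]


def recursive_elimination(
    table: pd.DataFrame, y: np.ndarray, target_n: int = 100,
    step: int = 1, seed: int = 0,
) -> list[str]:
    """Seeded linear-estimator RFE down to ``target_n`` features."""
    if step < 1:
        raise ValueError("step must be >= 1")
    cols = list(table.columns)
    if target_n >= len(cols):
        warnings.warn("target_n >= feature count: recursive elimination is a no-op")
        return cols
    est = LogisticRegression(max_iter=2000, random_state=seed)
    X = StandardScaler().fit_transform(table.to_numpy(dtype=float))
    rfe = RFE(est, n_features_to_select=target_n, step=step)
    rfe.fit(X, np.asarray(y))
    return [c for c, keep in zip(cols, rfe.support_) if keep]


def mrmr_select(
    table: pd.DataFrame, y: np.ndarray, target_n: int = 30,
    report: SelectionReport | None = None,
) -> list[str]:
    """Greedy minimum-redundancy maximum-relevance ranking (difference form).

    Relevance is the one-way F statistic against the class, normalized by its
    maximum so it shares the [0, 1] scale of the redundancy term (mean
    |Pearson r| with already-selected features).  The first pick is the most
    relevant feature; each later pick maximizes relevance minus redundancy,
    so an exact duplicate of a selected feature (redundancy 1) cannot win.
    """
    cols = list(table.columns)
    X = table.to_numpy(dtype=float)
    y = np.asarray(y)
    if target_n > len(cols):
        warnings.warn("target_n exceeds available features: truncating")
        target_n = len(cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        relevance = f_classif(X, y)[0]
    relevance = np.nan_to_num(relevance, nan=0.0)
    if relevance.max() > 0:
        relevance = relevance / relevance.max()
    with np.errstate(invalid="ignore"):
        corr = np.abs(np.corrcoef(X, rowvar=False))
    corr = np.nan_to_num(np.atleast_2d(corr), nan=1.0)

    selected: list[int] = [int(np.argmax(relevance))]
    while len(selected) < target_n:
        remaining = [i for i in range(len(cols)) if i not in selected]
        # near-duplicates of an already-selected feature (|r| >= 0.99) are
        # deferred: they carry no new information, so they are only taken
        # when nothing else remains
        fresh = [i for i in remaining if corr[i, selected].max() < 0.99]
        pool = fresh or remaining
        scores = [relevance[i] - corr[i, selected].mean() for i in pool]
        best = pool[int(np.argmax(scores))]
        selected.append(best)
    if report is not None:
        report.mrmr_scores = {cols[i]: float(relevance[i]) for i in selected}
    return [cols[i] for i in selected]


def lasso_select(
    table: pd.DataFrame, y: np.ndarray, cv_folds: int = 10,
    c_grid: np.ndarray | None = None, seed: int = 0,
    one_se_rule: bool = False,
    report: SelectionReport | None = None,
) -> tuple[list[str], dict[str, float]]:
    """L1 logistic regression over a C grid with stratified CV.

    Returns ``(nonzero feature names, Rad-score weights)``; the weights are
    on the internal z-scored scale.  When no coefficient survives, the
    ``no_signal`` flag is set and the caller falls back to the mRMR set.
    """
    cols = list(table.columns)
    y = np.asarray(y)
    if c_grid is None:
        c_grid = np.logspace(-3, 2, 30)
    scaler = StandardScaler()
    X = scaler.fit_transform(table.to_numpy(dtype=float))
    folds = min(cv_folds, int(np.bincount(y).min()))
    cv = StratifiedKFold(n_splits=max(folds, 2), shuffle=True, random_state=seed)
    model = LogisticRegressionCV(
        Cs=c_grid, cv=cv, penalty="l1", solver="liblinear",
        scoring="neg_log_loss", random_state=seed, max_iter=5000,
        refit=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    chosen_c = float(model.C_[0])
    if one_se_rule:
        scores = model.scores_[1]  # (folds, n_Cs)
        mean = scores.mean(axis=0)
        se = scores.std(axis=0, ddof=1) / np.sqrt(scores.shape[0])
        best = int(np.argmax(mean))
        ok = mean >= mean[best] - se[best]
        chosen_c = float(np.min(np.asarray(c_grid)[ok]))  # strongest penalty within 1 SE
        model = LogisticRegression(
            C=chosen_c, penalty="l1", solver="liblinear",
            random_state=seed, max_iter=5000,
        ).fit(X, y)
    coefs = np.ravel(model.coef_)
    nonzero = np.abs(coefs) > 1e-12
    survivors = [c for c, nz in zip(cols, nonzero) if nz]
    weights = {c: float(w) for c, w, nz in zip(cols, coefs, nonzero) if nz}
    if report is not None:
        report.lasso_c_grid = [float(c) for c in c_grid]
        report.chosen_c = chosen_c
        report.rad_score_weights = weights
        report.rad_score_intercept = float(np.ravel(model.intercept_)[0])
        report.no_signal = not survivors
    return survivors, weights


def run_selection_cascade(
    table: pd.DataFrame,
    y: np.ndarray,
    alpha: float = 0.05,
    corr_threshold: float = 0.9,
    rfe_target: int = 100,
    mrmr_target: int = 30,
    cv_folds: int = 10,
    seed: int = 0,
) -> SelectionReport:
    """Run all five stages on training rows; survivors are strictly nested."""
    report = SelectionReport()
    report.record("input", list(table.columns))

    s1 = significance_filter(table, y, alpha=alpha, report=report)
    report.record("significance", s1)
    if not s1:
        report.no_signal = True
        return report

    s2 = correlation_prune(table[s1], threshold=corr_threshold, report=report)
    report.record("correlation", s2)

    s3 = recursive_elimination(table[s2], y, target_n=min(rfe_target, len(s2)), seed=seed) \
        if len(s2) > rfe_target else s2
    report.record("rfe", s3)

    s4 = mrmr_select(table[s3], y, target_n=min(mrmr_target, len(s3)), report=report)
    report.record("mrmr", s4)

    s5, _ = lasso_select(table[s4], y, cv_folds=cv_folds, seed=seed, report=report)
    if not s5:
        warnings.warn("LASSO retained no features; falling back to the mRMR set")
        s5 = s4
    report.record("lasso", s5)
    return report
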
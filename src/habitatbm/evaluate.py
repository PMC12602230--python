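"""Model evaluation: DeLong AUC machinery, threshold metrics,
Hosmer-Lemeshow calibration, decision-curve analysis, Shapley attribution
and nomogram export.

AUC is the Mann-Whitney concordance (ties credited 0.5); its variance and
the paired two-model test use DeLong's structural components.  The default
operating threshold is Youden-optimal on the training cohort and frozen for
the other cohorts.  Decision curves report net benefit
``TP/n - (FP/n) * pt/(1-pt)`` against treat-all and treat-none policies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EvalReport",
    "AttributionReport",
    "auc_delong",
    "delong_test",
    "youden_threshold",
    "threshold_metrics",
    "hosmer_lemeshow",
    "decision_curve",
    "shapley_attribution",
    "nomogram_export",
    "evaluate_model",
]


# --------------------------------------------------------------------------
# DeLong machinery


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """Placement values V10 (per positive) and V01 (per negative)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    # psi(x, y) = 1 if x > y, 0.5 if x == y, 0 otherwise
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return psi.mean(axis=1), psi.mean(axis=0)


def auc_delong(scores, labels) -> tuple[float, float, tuple[float, float]]:
    """AUC, DeLong variance and Wald 95% CI (truncated to [0, 1])."""
    v10, v01 = _structural_components(scores, labels)
    auc = float(v10.mean())
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    se = float(np.sqrt(max(var, 0.0)))
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    return auc, float(var), ci


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Two-sided paired DeLong test for correlated AUCs; returns (z, p)."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if scores_a.shape != scores_b.shape or len(scores_a) != len(labels):
        raise ValueError("paired scores must have identical length matching labels")
    va10, va01 = _structural_components(scores_a, labels)
    vb10, vb01 = _structural_components(scores_b, labels)
    auc_a, auc_b = va10.mean(), vb10.mean()
    m, n = len(va10), len(va01)
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
    S = s10 / m + s01 / n
    var = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    diff = auc_a - auc_b
    if var <= 0:
        return (0.0, 1.0) if abs(diff) < 1e-12 else (float(np.sign(diff)) * np.inf, 0.0)
    z = float(diff / np.sqrt(var))
    p = float(2 * stats.norm.sf(abs(z)))
    return z, max(p, np.finfo(float).tiny)


# --------------------------------------------------------------------------
# Threshold metrics


def youden_threshold(scores, labels) -> float:
    """Threshold maximizing sensitivity + specificity - 1."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    cand = np.unique(scores)
    best_t, best_j = cand[0], -np.inf
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    for t in cand:
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        j = sens + spec - 1
        if j > best_j:
            best_j, best_t = j, t
    return float(best_t)


def threshold_metrics(scores, labels, threshold: float | None = None) -> dict[str, float]:
    """Confusion-matrix metrics at a threshold (default Youden on the data).

    When evaluating validation/test cohorts, pass the training-cohort
    threshold so the operating point stays frozen.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    if threshold is None:
        threshold = youden_threshold(scores, labels)
    if threshold < scores.min() or threshold > scores.max():
        import warnings

        warnings.warn("threshold outside score range: confusion matrix is degenerate")
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())

    def ratio(a, b):
        return a / b if b > 0 else 0.0

    return {
        "threshold": float(threshold),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "accuracy": (tp + tn) / len(labels),
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
    }


# --------------------------------------------------------------------------
# Calibration


def hosmer_lemeshow(probabilities, labels, groups: int = 10) -> tuple[float, float]:
    """Hosmer-Lemeshow chi-square with decile-of-risk grouping.

    Returns (statistic, p); p is from chi2 with ``groups - 2`` degrees of
    freedom (adjusted when groups merge).  Groups whose expected count is 0
    are merged with their neighbour.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    n = len(p)
    if n < 2 * groups:
        raise ValueError(f"need at least {2 * groups} observations for {groups} groups")
    order = np.argsort(p, kind="stable")
    p, y = p[order], y[order]
    edges = np.linspace(0, n, groups + 1).astype(int)
    bins = [(p[a:b], y[a:b]) for a, b in zip(edges[:-1], edges[1:]) if b > a]
    # merge zero-expectation groups into the next one
    merged: list[tuple[np.ndarray, np.ndarray]] = []
    carry_p, carry_y = np.array([]), np.array([])
    for bp, by in bins:
        bp = np.concatenate([carry_p, bp])
        by = np.concatenate([carry_y, by])
        e = bp.sum()
        if e == 0 or e == len(bp):  # degenerate expectation: merge onward
            carry_p, carry_y = bp, by
            continue
        merged.append((bp, by))
        carry_p, carry_y = np.array([]), np.array([])
    if carry_p.size:
        if merged:
            bp, by = merged[-1]
            merged[-1] = (np.concatenate([bp, carry_p]), np.concatenate([by, carry_y]))
        else:
            merged.append((carry_p, carry_y))
    stat = 0.0
    for bp, by in merged:
        ng = len(bp)
        e = bp.sum()
        o = by.sum()
        denom = e * (1 - e / ng)
        if denom > 0:
            stat += (o - e) ** 2 / denom
    df = max(len(merged) - 2, 1)
    return float(stat), float(stats.chi2.sf(stat, df))


def calibration_curve_points(probabilities, labels, bins: int = 10) -> pd.DataFrame:
    """Observed event fraction vs mean predicted probability per risk decile."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    order = np.argsort(p, kind="stable")
    p, y = p[order], y[order]
    edges = np.linspace(0, len(p), bins + 1).astype(int)
    rows = []
    for a, b in zip(edges[:-1], edges[1:]):
        if b > a:
            rows.append({"mean_predicted": p[a:b].mean(), "observed_fraction": y[a:b].mean(),
                         "n": b - a})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Decision curves


def decision_curve(
    probabilities, labels, threshold_grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Net benefit across decision thresholds, with treat-all/none references.

    net_benefit(pt) = TP/n - (FP/n) * pt/(1-pt); treat-all substitutes the
    whole cohort, treat-none is 0.  Thresholds must lie in (0, 1); pt = 1 is
    excluded.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if threshold_grid is None:
        threshold_grid = np.arange(0.01, 1.0, 0.01)
    threshold_grid = np.asarray(threshold_grid, dtype=float)
    threshold_grid = threshold_grid[(threshold_grid > 0) & (threshold_grid < 1)]
    n = len(y)
    prev = y.mean()
    rows = []
    for pt in threshold_grid:
        pred = p >= pt
        tp = float((pred & (y == 1)).sum())
        fp = float((pred & (y == 0)).sum())
        w = pt / (1 - pt)
        rows.append({
            "threshold": pt,
            "net_benefit": tp / n - (fp / n) * w,
            "treat_all": prev - (1 - prev) * w,
            "treat_none": 0.0,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Shapley attribution


@dataclass
class AttributionReport:
    """Per-sample feature contributions on the model's link (margin) scale
    for exact methods, probability scale for sampled attributions."""

    values: np.ndarray  # (n_samples, n_features)
    base_value: float
    feature_names: list[str]
    model_output: np.ndarray  # (n_samples,) on the same scale as values
    method: str

    def global_ranking(self) -> pd.Series:
        imp = np.abs(self.values).mean(axis=0)
        return pd.Series(imp, index=self.feature_names).sort_values(ascending=False)

    def local_accuracy_error(self) -> float:
        recon = self.base_value + self.values.sum(axis=1)
        return float(np.abs(recon - self.model_output).max())


def _linear_params(estimator):
    """Raw-scale (coef, intercept) for LogisticRegression, optionally scaled."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import Pipeline

    if isinstance(estimator, Pipeline):
        scaler = estimator.named_steps.get("scale")
        clf = estimator.steps[-1][1]
        if not isinstance(clf, LogisticRegression):
            return None
        w = np.ravel(clf.coef_).copy()
        b = float(np.ravel(clf.intercept_)[0])
        if scaler is not None:
            w = w / scaler.scale_
            b = b - float((w * scaler.mean_).sum())
        return w, b
    if isinstance(estimator, LogisticRegression):
        return np.ravel(estimator.coef_).copy(), float(np.ravel(estimator.intercept_)[0])
    return None


def shapley_attribution(
    model,
    rows: pd.DataFrame,
    background: pd.DataFrame,
    n_permutations: int = 64,
    seed: int = 0,
) -> AttributionReport:
    """Shapley feature attributions for a fitted model.

    Linear models get exact linear SHAP on the logit scale; xgboost/lightgbm
    tree ensembles use their native exact tree-path contributions (also
    margin scale); anything else falls back to seeded permutation sampling
    in probability space.  For the exact methods
    ``base + sum(contributions) = model output`` to 1e-6 per sample.
    """
    from .modeling import FittedModel, predict as model_predict

    if background is None or len(background) == 0:
        raise ValueError("background sample must be nonempty")
    if isinstance(model, FittedModel):
        names = model.signature.features
        estimator = model.estimator
        X = rows[names].to_numpy(dtype=float)
        B = background[names].to_numpy(dtype=float)
    else:
        estimator = model
        names = list(rows.columns)
        X = rows.to_numpy(dtype=float)
        B = background[names].to_numpy(dtype=float)

    lin = _linear_params(estimator)
    if lin is not None:
        w, b = lin
        mu = B.mean(axis=0)
        vals = w[None, :] * (X - mu[None, :])
        base = float(w @ mu + b)
        margin = X @ w + b
        return AttributionReport(vals, base, list(names), margin, method="linear_exact")

    cls_name = type(estimator).__name__
    if cls_name == "XGBClassifier":
        import xgboost as xgb

        booster = estimator.get_booster()
        contrib = booster.predict(xgb.DMatrix(X, feature_names=None), pred_contribs=True)
        vals, base = contrib[:, :-1], float(contrib[0, -1])
        margin = estimator.predict(X, output_margin=True)
        return AttributionReport(vals, base, list(names), np.asarray(margin, float),
                                 method="tree_exact")
    if cls_name == "LGBMClassifier":
        contrib = estimator.predict(X, pred_contrib=True)
        vals, base = contrib[:, :-1], float(contrib[0, -1])
        margin = estimator.predict(X, raw_score=True)
        return AttributionReport(vals, base, list(names), np.asarray(margin, float),
                                 method="tree_exact")

    # Sampling-based permutation Shapley in probability space.
    rng = np.random.default_rng(seed)
    n, p = X.shape

    def f(mat: np.ndarray) -> np.ndarray:
        return estimator.predict_proba(mat)[:, 1]

    base = float(f(B).mean())
    vals = np.zeros((n, p))
    for _ in range(n_permutations):
        perm = rng.permutation(p)
        bg = B[rng.integers(0, len(B), size=n)]
        cur = bg.copy()
        prev_out = f(cur)
        for j in perm:
            cur[:, j] = X[:, j]
            out = f(cur)
            vals[:, j] += out - prev_out
            prev_out = out
    vals /= n_permutations
    return AttributionReport(vals, base, list(names), f(X), method="permutation_sampled")


# --------------------------------------------------------------------------
# Nomogram


@dataclass
class Nomogram:
    """Points-based rendering of a logistic model."""

    coefficients: dict[str, float]
    intercept: float
    ranges: dict[str, tuple[float, float]]
    points_per_unit: dict[str, float] = field(default_factory=dict)
    reference: dict[str, float] = field(default_factory=dict)
    scale: float = 1.0

    def points(self, row: dict | pd.Series) -> float:
        return float(sum(
            self.points_per_unit[f] * (float(row[f]) - self.reference[f])
            for f in self.coefficients
        ))

    def probability_from_points(self, total_points: float) -> float:
        eta = total_points / self.scale + self.intercept + sum(
            self.coefficients[f] * self.reference[f] for f in self.coefficients
        )
        return float(1.0 / (1.0 + np.exp(-eta)))

    def probability(self, row: dict | pd.Series) -> float:
        return self.probability_from_points(self.points(row))

    def table(self) -> pd.DataFrame:
        rows = []
        for f, beta in self.coefficients.items():
            lo, hi = self.ranges[f]
            rows.append({
                "predictor": f, "coefficient": beta,
                "range_low": lo, "range_high": hi,
                "points_at_low": self.points_per_unit[f] * (lo - self.reference[f]),
                "points_at_high": self.points_per_unit[f] * (hi - self.reference[f]),
                "max_points": abs(beta) * (hi - lo) * self.scale,
            })
        return pd.DataFrame(rows).set_index("predictor")


def nomogram_export(
    model_or_coefs,
    ranges: dict[str, tuple[float, float]],
    intercept: float | None = None,
) -> Nomogram:
    """Points table for a logistic (linear) combined model.

    Each predictor's points are linear in coefficient x value, referenced at
    the range end contributing least risk and scaled so the largest
    single-predictor span equals 100 points.  Total points map back to the
    predicted probability through the inverse logit exactly.
    """
    if isinstance(model_or_coefs, dict):
        coefs = dict(model_or_coefs)
        if intercept is None:
            raise ValueError("intercept required when passing raw coefficients")
        b0 = float(intercept)
    else:
        from .modeling import FittedModel

        est = model_or_coefs.estimator if isinstance(model_or_coefs, FittedModel) else model_or_coefs
        lin = _linear_params(est)
        if lin is None:
            raise ValueError(
                "nomogram requires a logistic (linear) model; "
                "use a score-level nomogram for non-linear models"
            )
        w, b0 = lin
        names = (model_or_coefs.signature.features
                 if isinstance(model_or_coefs, FittedModel) else list(ranges))
        coefs = {f: float(wi) for f, wi in zip(names, w)}

    spans = {f: abs(coefs[f]) * (ranges[f][1] - ranges[f][0]) for f in coefs}
    max_span = max(spans.values())
    if max_span <= 0:
        raise ValueError("all predictors have zero span")
    scale = 100.0 / max_span  # points per logit unit
    nomo = Nomogram(coefficients=coefs, intercept=b0, ranges=dict(ranges), scale=scale)
    for f, beta in coefs.items():
        lo, hi = ranges[f]
        nomo.reference[f] = lo if beta >= 0 else hi
        nomo.points_per_unit[f] = beta * scale
    return nomo


# --------------------------------------------------------------------------
# Report assembly


@dataclass
class EvalReport:
    """Full per-model, per-cohort evaluation summary."""

    auc: float
    auc_variance: float
    ci: tuple[float, float]
    metrics: dict[str, float]
    hl_statistic: float
    hl_p: float
    calibration: pd.DataFrame
    dca: pd.DataFrame

    def summary_row(self) -> dict[str, float]:
        return {
            "Accuracy": self.metrics["accuracy"],
            "AUC": self.auc,
            "CI_low": self.ci[0],
            "CI_high": self.ci[1],
            "Sensitivity": self.metrics["sensitivity"],
            "Specificity": self.metrics["specificity"],
            "PPV": self.metrics["ppv"],
            "NPV": self.metrics["npv"],
            "HL_statistic": self.hl_statistic,
            "HL_p": self.hl_p,
        }


def evaluate_model(
    scores, labels, threshold: float | None = None, hl_groups: int = 10
) -> EvalReport:
    """Assemble the full evaluation report for one cohort's frozen scores."""
    auc, var, ci = auc_delong(scores, labels)
    metrics = threshold_metrics(scores, labels, threshold)
    try:
        hl_stat, hl_p = hosmer_lemeshow(scores, labels, groups=hl_groups)
    except ValueError:
        hl_stat, hl_p = float("nan"), float("nan")
    return EvalReport(
        auc=auc,
        auc_variance=var,
        ci=ci,
        metrics=metrics,
        hl_statistic=hl_stat,
        hl_p=hl_p,
        calibration=calibration_curve_points(scores, labels),
        dca=decision_curve(scores, labels),
    )
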
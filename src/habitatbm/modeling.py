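"""Per-signature predictive models with strict train-only fitting.

Six algorithm families (logistic regression, SVM, random forest, extra
trees, and two gradient-boosting variants via xgboost and lightgbm) are fit
on training rows with a small seeded cross-validated hyperparameter grid;
the fitted model freezes its feature list and is applied unchanged to
validation/test cohorts.  The "combined" signature concatenates the habitat
and optimal-peritumoral survivor sets with the significant clinical
covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ALGORITHMS",
    "SignatureSpec",
    "FittedModel",
    "train_model",
    "predict",
    "compare_algorithms",
]

ALGORITHMS = ("LR", "SVM", "RandomForest", "ExtraTrees", "XGBoost", "LightGBM")


def _estimator_and_grid(algorithm: str, seed: int):
    if algorithm == "LR":
        est = Pipeline([
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(max_iter=5000, random_state=seed)),
        ])
        grid = {"clf__C": [0.01, 0.1, 1.0, 10.0]}
    elif algorithm == "SVM":
        from sklearn.calibration import CalibratedClassifierCV

        est = Pipeline([
            ("scale", StandardScaler()),
            ("clf", CalibratedClassifierCV(SVC(random_state=seed), ensemble=False, cv=3)),
        ])
        grid = {"clf__estimator__C": [0.1, 1.0, 10.0]}
    elif algorithm == "RandomForest":
        est = RandomForestClassifier(random_state=seed)
        grid = {"n_estimators": [100, 300], "max_depth": [3, 5, None]}
    elif algorithm == "ExtraTrees":
        est = ExtraTreesClassifier(random_state=seed)
        grid = {"n_estimators": [100, 300], "max_depth": [3, 5, None]}
    elif algorithm == "XGBoost":
        from xgboost import XGBClassifier

        est = XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss",
            tree_method="hist",
        )
        grid = {"max_depth": [2, 3, 4], "n_estimators": [100, 300],
                "learning_rate": [0.1]}
    elif algorithm == "LightGBM":
        from lightgbm import LGBMClassifier

        est = LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1)
        grid = {"max_depth": [2, 3, 4], "n_estimators": [100, 300],
                "learning_rate": [0.1]}
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    return est, grid


@dataclass
class SignatureSpec:
    """A named feature signature (which columns feed a model)."""

    source: str  # radiomics | peri-1mm | peri-2mm | peri-3mm | habitat | clinical | combined
    features: list[str]

    @classmethod
    def combined(
        cls,
        habitat_features: list[str],
        peritumoral_features: list[str],
        clinical_features: list[str],
    ) -> "SignatureSpec":
        feats = list(dict.fromkeys(habitat_features + peritumoral_features + clinical_features))
        return cls(source="combined", features=feats)


@dataclass
class FittedModel:
    """Frozen fitted classifier with its signature and training metadata."""

    algorithm: str
    signature: SignatureSpec
    estimator: object
    seed: int
    cv_folds: int
    training_cohort_id: str = "train"
    best_params: dict = field(default_factory=dict)
    training_predictions: pd.Series | None = None


def train_model(
    table: pd.DataFrame,
    y: np.ndarray,
    signature: SignatureSpec,
    algorithm: str = "XGBoost",
    cv_folds: int = 5,
    seed: int = 0,
    tune: bool = True,
) -> FittedModel:
    """Fit one algorithm on training rows with a small seeded CV grid."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    missing = [f for f in signature.features if f not in table.columns]
    if missing:
        raise ValueError(f"training table lacks signature features: {missing[:5]}")
    X = table[signature.features].to_numpy(dtype=float)
    est, grid = _estimator_and_grid(algorithm, seed)
    if tune and all(len(v) > 0 for v in grid.values()):
        folds = min(cv_folds, int(np.bincount(y).min()))
        cv = StratifiedKFold(n_splits=max(folds, 2), shuffle=True, random_state=seed)
        search = GridSearchCV(est, grid, cv=cv, scoring="roc_auc", n_jobs=1)
        search.fit(X, y)
        fitted = search.best_estimator_
        best = search.best_params_
    else:
        fitted = est.fit(X, y)
        best = {}
    model = FittedModel(
        algorithm=algorithm, signature=signature, estimator=fitted,
        seed=seed, cv_folds=cv_folds, best_params=best,
    )
    model.training_predictions = pd.Series(
        fitted.predict_proba(X)[:, 1], index=table.index
    )
    return model


def predict(model: FittedModel, table: pd.DataFrame) -> np.ndarray:
    """Apply a frozen model; never refits, never silently imputes."""
    missing = [f for f in model.signature.features if f not in table.columns]
    if missing:
        raise ValueError(f"prediction table lacks required features: {missing[:5]}")
    X = table[model.signature.features].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("prediction rows contain non-finite feature values")
    return model.estimator.predict_proba(X)[:, 1]


def compare_algorithms(
    train_table: pd.DataFrame,
    y_train: np.ndarray,
    signature: SignatureSpec,
    eval_cohorts: dict[str, tuple[pd.DataFrame, np.ndarray]],
    algorithms: tuple[str, ...] = ALGORITHMS,
    cv_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit each algorithm and rank by mean AUC over the evaluation cohorts.

    Returns a DataFrame (one row per algorithm, sorted best first) with
    per-cohort AUC + 95% CI columns and the mean AUC used for ranking.
    """
    from .evaluate import auc_delong

    rows = []
    models = {}
    for algo in algorithms:
        model = train_model(
            train_table, y_train, signature, algorithm=algo,
            cv_folds=cv_folds, seed=seed,
        )
        models[algo] = model
        row: dict[str, float | str] = {"algorithm": algo}
        aucs = []
        for name, (tbl, yy) in eval_cohorts.items():
            scores = predict(model, tbl)
            auc, _, (lo, hi) = auc_delong(scores, yy)
            row[f"{name}_auc"] = auc
            row[f"{name}_ci_low"] = lo
            row[f"{name}_ci_high"] = hi
            aucs.append(auc)
        row["mean_auc"] = float(np.mean(aucs)) if aucs else float("nan")
        rows.append(row)
    report = pd.DataFrame(rows).set_index("algorithm")
    report = report.sort_values("mean_auc", ascending=False)
    report.attrs["models"] = models
    return report
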
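"""Clinical covariate engineering, cohort splitting, and logistic modelling.

Derived indices: the prognostic nutritional index PNI = albumin (g/L) +
5 x absolute lymphocyte count (10^9/L), and the systemic inflammation
response index SIRI = neutrophils x monocytes / lymphocytes.  Cohorts are
split stratified on the response (default 7:3).  Univariable logistic fits
screen covariates at alpha; significant covariates (plus any forced-in) then
enter one multivariable fit.  Odds ratios are exponentiated coefficients
with Wald 95% confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import train_test_split

__all__ = [
    "derive_indices",
    "add_derived_indices",
    "split_cohort",
    "uni_multi_logistic",
    "OddsTable",
]


def derive_indices(row: dict | pd.Series) -> tuple[float, float]:
    """Compute (PNI, SIRI) for one patient record.

    PNI = albumin + 5 x lymphocytes; SIRI = neutrophils x monocytes /
    lymphocytes.  SIRI is NaN (flagged missing) when lymphocytes <= 0; PNI
    is still computed.
    """
    albumin = float(row["albumin"])
    lymph = float(row["lymphocyte"])
    neut = float(row["neutrophil"])
    mono = float(row["monocyte"])
    pni = albumin + 5.0 * lymph
    if lymph <= 0:
        warnings.warn("lymphocyte count <= 0: SIRI set to missing")
        return pni, float("nan")
    return pni, neut * mono / lymph


def add_derived_indices(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the table with recomputed ``pni``/``siri`` columns."""
    out = table.copy()
    derived = out.apply(derive_indices, axis=1, result_type="expand")
    out["pni"], out["siri"] = derived[0], derived[1]
    return out


def split_cohort(
    table: pd.DataFrame,
    ratio: float = 0.7,
    stratify_col: str = "response",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified random split into (train, validation).

    Train size is ``round(ratio * n)``; deterministic given the seed.  A
    209-row table at ratio 0.7 yields 146/63.
    """
    n = len(table)
    if n < 10:
        raise ValueError("need at least 10 rows to split")
    n_train = int(round(ratio * n))
    y = table[stratify_col]
    train, val = train_test_split(
        table, train_size=n_train, stratify=y, random_state=seed
    )
    for part, name in ((train, "train"), (val, "validation")):
        if part[stratify_col].nunique() < 2:
            raise ValueError(f"{name} split lost a response class; cohort too small")
    return train, val


@dataclass
class OddsTable:
    """Per-covariate odds ratios from univariable and multivariable fits."""

    univariable: pd.DataFrame = field(default_factory=pd.DataFrame)
    multivariable: pd.DataFrame = field(default_factory=pd.DataFrame)
    significant: list[str] = field(default_factory=list)
    separation_flagged: list[str] = field(default_factory=list)

    def to_csv(self, path_uni: str, path_multi: str) -> None:
        self.univariable.to_csv(path_uni)
        self.multivariable.to_csv(path_multi)


def _fit_logit(X: pd.DataFrame, y: np.ndarray):
    """Logit fit; returns (params, conf_int, pvalues, separation_flag)."""
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            # separation heuristic on the linear-predictor scale (covariate
            # effects measured in SDs, so small-unit covariates do not
            # trigger it)
            scale = Xc.std(axis=0).replace(0, 1.0)
            effect_sds = np.abs(res.params.drop("const")) * scale.drop("const")
            separated = bool(
                np.any(effect_sds > 20) or not res.mle_retvals["converged"]
            )
        except Exception:
            res = None
            separated = True
        if separated:
            # quasi-separation: ridge-penalized fallback; Wald CIs from the
            # penalized information matrix are approximate and flagged.
            res = sm.Logit(y, Xc).fit_regularized(
                disp=0, alpha=1.0, L1_wt=0.0, maxiter=500
            )
            params = res.params
            return params, None, None, True
    return res.params, res.conf_int(alpha=0.05), res.pvalues, False


def uni_multi_logistic(
    table: pd.DataFrame,
    y: np.ndarray | str = "response",
    alpha: float = 0.05,
    forced_in: list[str] | None = None,
    covariates: list[str] | None = None,
) -> OddsTable:
    """Univariable screening plus one multivariable logistic fit.

    Each covariate is fit alone (OR, Wald 95% CI, p); covariates with
    p < alpha plus any ``forced_in`` enter the multivariable model.
    Separation triggers a penalized fallback with the covariate flagged.
    """
    if isinstance(y, str):
        yv = table[y].to_numpy(dtype=float)
        covs = covariates or [c for c in table.columns if c != y]
    else:
        yv = np.asarray(y, dtype=float)
        covs = covariates or list(table.columns)
    forced_in = forced_in or []
    out = OddsTable()

    rows = []
    for c in covs:
        X = table[[c]].astype(float)
        params, ci, pv, flagged = _fit_logit(X, yv)
        orv = float(np.exp(params[c]))
        if flagged:
            out.separation_flagged.append(c)
            rows.append({"covariate": c, "OR": orv, "CI_low": np.nan,
                         "CI_high": np.nan, "p": np.nan})
        else:
            rows.append({
                "covariate": c,
                "OR": orv,
                "CI_low": float(np.exp(ci.loc[c, 0])),
                "CI_high": float(np.exp(ci.loc[c, 1])),
                "p": float(pv[c]),
            })
    out.univariable = pd.DataFrame(rows).set_index("covariate")

    sig = [
        c for c in covs
        if np.isfinite(out.univariable.loc[c, "p"]) and out.univariable.loc[c, "p"] < alpha
    ]
    multi_covs = list(dict.fromkeys(sig + [f for f in forced_in if f in covs]))
    out.significant = multi_covs
    if multi_covs:
        X = table[multi_covs].astype(float)
        params, ci, pv, flagged = _fit_logit(X, yv)
        rows = []
        for c in multi_covs:
            if flagged:
                rows.append({"covariate": c, "OR": float(np.exp(params[c])),
                             "CI_low": np.nan, "CI_high": np.nan, "p": np.nan})
            else:
                rows.append({
                    "covariate": c,
                    "OR": float(np.exp(params[c])),
                    "CI_low": float(np.exp(ci.loc[c, 0])),
                    "CI_high": float(np.exp(ci.loc[c, 1])),
                    "p": float(pv[c]),
                })
        if flagged:
            out.separation_flagged.append("__multivariable__")
        out.multivariable = pd.DataFrame(rows).set_index("covariate")
    return out
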
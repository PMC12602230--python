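"""End-to-end orchestration: simulate/ingest -> preprocess -> habitat ->
regions -> features -> selection -> models -> evaluation.

Produces, per signature (clinical, intratumoral radiomics, peri-1/2/3 mm,
habitat, combined) and per cohort, an evaluation summary table shaped like a
classic multi-model performance table (Accuracy, AUC + CI, sensitivity,
specificity, PPV, NPV, HL).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clinical as clin
from . import evaluate as ev
from .features import FeatureConfig, build_feature_table, extract_patient_features, fuse_habitat_features
from .habitat import LocalFeatureMap, assign_habitats, fit_habitats, local_features, select_k, subsample_voxels
from .modeling import FittedModel, SignatureSpec, predict, train_model
from .preprocess import correct_bias, resample_isotropic
from .regions import build_region_set
from .selection import SelectionReport, run_selection_cascade
from .synthdata import SyntheticPatient

CLINICAL_COVARIATES = [
    "age", "gender_male", "smoking", "ici_line_gt2", "anti_pd1", "chemo_combo",
    "ecog_ge2", "pathology_adeno", "pdl1_gt50", "n_met_sites", "multiple_bm",
    "t_stage_34", "n_stage_34", "m_stage_34", "rbc", "wbc", "platelet", "ldh",
    "cea", "ca125", "ca199", "pni", "siri",
]


@dataclass
class PipelineConfig:
    """Desk-scale defaults for a full run."""

    feature_config: FeatureConfig = field(default_factory=FeatureConfig.minimal)
    radii: tuple[float, ...] = (1.0, 2.0, 3.0)
    k_range: tuple[int, int] = (3, 10)
    n_kmeans_seeds: int = 10
    subsample_per_patient: int = 1000
    max_k_selection_voxels: int = 3000
    algorithm: str = "XGBoost"
    split_ratio: float = 0.7
    bias_correction: bool = True
    alpha: float = 0.05
    rfe_target: int = 50
    mrmr_target: int = 20
    lasso_cv_folds: int = 5
    forced_in_clinical: list[str] = field(default_factory=lambda: ["gender_male"])
    seed: int = 0


@dataclass
class PipelineResult:
    k_star: int
    k_diagnostics: dict
    habitat_consistency: float
    selection_reports: dict[str, SelectionReport]
    models: dict[str, FittedModel]
    thresholds: dict[str, float]
    feature_tables: dict[str, pd.DataFrame]
    clinical_odds: clin.OddsTable
    summary: pd.DataFrame  # cohort x signature metric table
    cohorts: dict[str, pd.DataFrame]
    scores: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)


def _preprocess_patient(p: SyntheticPatient, cfg: PipelineConfig):
    vol, mask = p.volume, p.mask
    if cfg.bias_correction:
        vol, _ = correct_bias(vol, mask=None, n_levels=2, on_nonpositive="shift")
    return resample_isotropic(vol, mask, target_mm=1.0)


def run_pipeline(patients: list[SyntheticPatient], cfg: PipelineConfig | None = None) -> PipelineResult:
    """Run the full analysis on an in-memory cohort; see module docstring."""
    cfg = cfg or PipelineConfig()
    rng_seed = cfg.seed

    clinical_df = pd.DataFrame(
        [{"patient_id": p.patient_id, **p.clinical_row} for p in patients]
    ).set_index("patient_id")
    clinical_df = clin.add_derived_indices(clinical_df)
    y_all = clinical_df["response"].astype(int)

    train_df, val_df = clin.split_cohort(
        clinical_df.reset_index(), ratio=cfg.split_ratio, seed=rng_seed
    )
    train_ids = train_df["patient_id"].tolist()
    val_ids = val_df["patient_id"].tolist()

    # ---- preprocessing + local feature maps --------------------------------
    preprocessed: dict[str, tuple] = {}
    fmaps: dict[str, LocalFeatureMap] = {}
    for p in patients:
        vol, mask = _preprocess_patient(p, cfg)
        preprocessed[p.patient_id] = (vol, mask)
        fmaps[p.patient_id] = local_features(vol, mask)

    # ---- habitat model (training voxels only) ------------------------------
    train_maps = [fmaps[i] for i in train_ids]
    pooled = subsample_voxels(train_maps, cfg.subsample_per_patient, seed=rng_seed)
    if pooled.shape[0] > cfg.max_k_selection_voxels:
        sel = np.random.default_rng(rng_seed).choice(
            pooled.shape[0], cfg.max_k_selection_voxels, replace=False
        )
        pooled_k = pooled[sel]
    else:
        pooled_k = pooled
    mu, sd = pooled_k.mean(axis=0), pooled_k.std(axis=0)
    Z = (pooled_k[:, sd > 1e-12] - mu[sd > 1e-12]) / sd[sd > 1e-12]
    k_star, k_diag = select_k(Z, k_range=cfg.k_range, n_seeds=cfg.n_kmeans_seeds,
                              base_seed=rng_seed)
    hmodel = fit_habitats(train_maps, k=k_star, n_seeds=cfg.n_kmeans_seeds,
                          subsample_per_patient=cfg.subsample_per_patient, seed=rng_seed)

    # ---- regions + feature extraction --------------------------------------
    region_rows: dict[str, list[dict]] = {}
    fused_rows: list[dict] = []
    ids = []
    for p in patients:
        vol, mask = preprocessed[p.patient_id]
        habitat_map = assign_habitats(hmodel, fmaps[p.patient_id])
        rset = build_region_set(mask, habitat_map, radii=cfg.radii)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vecs = extract_patient_features(vol, rset, cfg.feature_config)
        ids.append(p.patient_id)
        for rname, vec in vecs.items():
            if rname.startswith("habitat"):
                continue
            region_rows.setdefault(rname, []).append(vec or {})
        per_hab = {h: vecs.get(f"habitat{h}") for h in range(1, k_star + 1)}
        fused, _missing = fuse_habitat_features(per_hab, k=k_star)
        fused_rows.append(fused)

    tables: dict[str, pd.DataFrame] = {}
    name_map = {"tumor": "Radiomics"}
    for r in cfg.radii:
        name_map[f"peri{r:g}mm"] = f"Peri-{r:g}mm"
    for rname, rows in region_rows.items():
        tables[name_map[rname]] = build_feature_table(rows, index=ids).fillna(0.0)
    tables["Habitat"] = build_feature_table(fused_rows, index=ids)
    tables["Clinical"] = clinical_df[CLINICAL_COVARIATES].astype(float)

    # ---- clinical model -----------------------------------------------------
    clin_train = tables["Clinical"].loc[train_ids]
    odds = clin.uni_multi_logistic(
        clin_train.assign(response=y_all.loc[train_ids].values),
        y="response", alpha=cfg.alpha, forced_in=cfg.forced_in_clinical,
        covariates=CLINICAL_COVARIATES,
    )
    clinical_features = odds.significant or cfg.forced_in_clinical

    # ---- selection + models per signature ----------------------------------
    y_train = y_all.loc[train_ids].to_numpy()
    y_val = y_all.loc[val_ids].to_numpy()
    sel_reports: dict[str, SelectionReport] = {}
    models: dict[str, FittedModel] = {}
    thresholds: dict[str, float] = {}
    summary_rows = []
    scores_store: dict[tuple[str, str], np.ndarray] = {}

    imaging_signatures = ["Radiomics"] + [name_map[f"peri{r:g}mm"] for r in cfg.radii] + ["Habitat"]
    survivor_sets: dict[str, list[str]] = {}
    for sig in imaging_signatures:
        tbl = tables[sig]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = run_selection_cascade(
                tbl.loc[train_ids], y_train, alpha=cfg.alpha,
                rfe_target=cfg.rfe_target, mrmr_target=cfg.mrmr_target,
                cv_folds=cfg.lasso_cv_folds, seed=rng_seed,
            )
        sel_reports[sig] = rep
        survivor_sets[sig] = rep.selected or list(tbl.columns[: cfg.mrmr_target])

    # combined = habitat survivors + peri-1mm survivors + significant clinical
    peri1 = name_map.get(f"peri{cfg.radii[0]:g}mm", "Peri-1mm")
    combined_table = pd.concat(
        [tables["Habitat"], tables[peri1], tables["Clinical"]], axis=1
    )
    combined_features = list(dict.fromkeys(
        survivor_sets["Habitat"] + survivor_sets[peri1] + clinical_features
    ))

    specs = {sig: SignatureSpec(sig, survivor_sets[sig]) for sig in imaging_signatures}
    specs["Clinical"] = SignatureSpec("Clinical", clinical_features)
    specs["Combined"] = SignatureSpec("combined", combined_features)
    model_tables = {sig: tables[sig] for sig in imaging_signatures}
    model_tables["Clinical"] = tables["Clinical"]
    model_tables["Combined"] = combined_table

    cohorts = {"Training": train_ids, "Validation": val_ids}
    for sig, spec in specs.items():
        tbl = model_tables[sig]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = train_model(
                tbl.loc[train_ids], y_train, spec,
                algorithm="LR" if sig == "Clinical" else cfg.algorithm,
                cv_folds=3, seed=rng_seed,
            )
        models[sig] = model
        s_train = predict(model, tbl.loc[train_ids])
        thr = ev.youden_threshold(s_train, y_train)
        thresholds[sig] = thr
        for cname, cids in cohorts.items():
            yv = y_all.loc[cids].to_numpy()
            s = predict(model, tbl.loc[cids])
            scores_store[(sig, cname)] = s
            rep = ev.evaluate_model(s, yv, threshold=thr)
            summary_rows.append({"Cohort": cname, "Signature": sig, **rep.summary_row()})

    summary = pd.DataFrame(summary_rows).set_index(["Cohort", "Signature"])
    return PipelineResult(
        k_star=k_star,
        k_diagnostics=k_diag,
        habitat_consistency=hmodel.consistency,
        selection_reports=sel_reports,
        models=models,
        thresholds=thresholds,
        feature_tables=tables,
        clinical_odds=odds,
        summary=summary,
        cohorts={"Training": clinical_df.loc[train_ids], "Validation": clinical_df.loc[val_ids]},
        scores=scores_store,
    )
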
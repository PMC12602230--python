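# habitatbm

Habitat and peritumoral radiomics for predicting intracranial treatment
response from brain-metastasis MRI.

## The problem

Whether a brain metastasis will respond to systemic therapy is hard to read
off a single pre-treatment MRI, because tumors are not homogeneous: they are
spatial mosaics of phenotypically distinct subregions ("habitats" —
enhancing, intermediate, necrotic-like), and the few millimetres of tissue
just outside the tumor margin carry their own microenvironmental signal.
`habitatbm` implements the full imaging-biomarker pipeline for this setting,
for researchers building or stress-testing habitat/peritumoral radiomics
models:

1. **Preprocessing** — log-domain multiplicative bias-field correction
   (N4-style; the corrected image is `I / B̂` with `B̂` a smooth field),
   1×1×1 mm isotropic resampling (B-spline for images, nearest-neighbour for
   masks), dominant-lesion selection, and ICC(2,1) observer agreement.
2. **Habitat discovery** — every lesion voxel is summarized by 19 first-order
   statistics of its 5×5×5 neighbourhood; voxels pooled across the training
   cohort are standardized and clustered with K-means. The cluster count
   `k*` is chosen by consensus of the Calinski–Harabasz, Davies–Bouldin and
   Silhouette indices over `k = 3..10`, each refit with 10 random seeds, and
   the solution's stability is reported as the mean pairwise voxel-assignment
   agreement after Hungarian label matching.
3. **Peritumoral rings** at 1/2/3 mm, built from the exact Euclidean
   distance transform in physical mm.
4. **Radiomics** — an IBSI-style extractor producing exactly **1,834
   features per region**: 14 shape descriptors + 91 intensity/texture
   features (18 first-order, 22 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM)
   on each of 20 image types (original, 8 wavelet sub-bands, 6
   Laplacian-of-Gaussian scales, square, square-root, logarithm,
   exponential, gradient). Early fusion of `k = 3` habitats gives 5,502
   columns.
5. **Feature selection** — significance filter (Shapiro–Wilk decides t-test
   vs Mann–Whitney U, keep `p < 0.05`) → correlation pruning at
   `|r| ≥ 0.9` → recursive feature elimination → mRMR → L1-penalized
   logistic regression with cross-validated penalty (the survivors define a
   Rad-score).
6. **Models** — per-signature classifiers (logistic regression, SVM, random
   forest, extra trees, XGBoost- and LightGBM-style gradient boosting) with
   strict train-only fitting; a combined model concatenates the habitat and
   optimal-peritumoral survivors with significant clinical covariates
   (including PNI = albumin + 5 × lymphocytes and
   SIRI = neutrophils × monocytes / lymphocytes).
7. **Evaluation** — AUC with DeLong variance and CI, paired DeLong tests,
   Youden-thresholded confusion metrics frozen from the training cohort,
   Hosmer–Lemeshow calibration, decision-curve analysis
   (`NB(p_t) = TP/n − FP/n · p_t/(1−p_t)`), Shapley attribution (exact for
   linear and tree models), and nomogram export.

Because no patient data are distributed, the package ships a first-class
**synthetic cohort generator** (`habitatbm.synthdata`): lesions with three
latent phenotype subregions of known intensity/texture statistics, a
peritumoral intensity halo, smooth multiplicative bias fields, anisotropic
native spacing, and a clinical table whose binary response follows a
documented logistic model. Every pipeline stage is tested against these
known ground truths.

## Worked example

```bash
python examples/full_pipeline.py
```

runs the complete analysis on a 60-patient synthetic cohort and prints

```
selected cluster count k* = 3
habitat assignment consistency = 0.999
significant clinical covariates: ['gender_male']
...
                      Accuracy    AUC  CI_low  CI_high  Sensitivity  Specificity    PPV    NPV
Cohort     Signature
Validation Radiomics     0.667  0.606   0.324    0.888        0.500        0.800  0.667  0.667
Validation Peri-1mm      0.667  0.669   0.378    0.959        0.375        0.900  0.750  0.643
Validation Habitat       0.778  0.862   0.666    1.000        0.625        0.900  0.833  0.750
Validation Clinical      0.556  0.525   0.318    0.732        0.250        0.800  0.500  0.571
Validation Combined      0.611  0.850   0.653    1.000        0.250        0.900  0.667  0.600
```

Reading this: the three validity indices agree that the voxel-feature cloud
has three clusters (the number of generating phenotypes), and the habitat
definition is stable across K-means seeds (99.9% matched agreement). On the
held-out validation split, the habitat signature discriminates responders
best (AUC 0.862) — the generator plants the response signal in the
habitat-2 volume fraction — while whole-tumor and peritumoral signatures
carry weaker signal and the clinical model is near its planted effect size.
Training rows score perfectly because gradient boosting interpolates 42
patients; the validation columns are the honest numbers.

The other scripts in `examples/` each exercise one capability
(`simulate_cohort.py`, `habitat_discovery.py`, `peritumoral_rings.py`,
`radiomics_features.py`, `feature_selection.py`, `clinical_model.py`,
`model_evaluation.py`).

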
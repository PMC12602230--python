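# Methods

This note documents the models, defaults and numerical choices behind
`habitatbm`, and what the synthetic-cohort experiments do and do not
establish.

## Synthetic cohort generator

The generator (`habitatbm.synthdata`) emulates a contrast-MRI
brain-metastasis cohort at desk scale. Per patient:

- **Lesion geometry.** An ellipsoid with per-axis radii drawn from a
  diameter range of 8–30 mm (the clinical inclusion floor for measurable
  metastases is 5 mm; the upper end keeps volumes desk-sized), jittered
  ±15% per axis, embedded in a background grid with an 11 mm margin at the
  native spacing (default 0.9 × 0.9 × 5.0 mm, anisotropic so resampling is
  exercised).
- **Phenotype subregions.** Lesion voxels are ranked by a smooth scalar
  field (projection onto a random axis plus 10% smooth noise) and cut at
  per-patient volume-fraction quantiles, producing connected slab-shaped
  subregions. Slabs keep each subregion at least roughly
  `fraction × diameter` thick; concentric shells were rejected because the
  outer shells of a 50/30/20 split are thinner than a 5×5×5 local-feature
  window, making voxel-level recovery ill-posed by construction. Default
  phenotypes: means 180/140/100 intensity units (4 noise-SDs apart), SD 10,
  texture correlation lengths 0.6/1.5/3.0 mm, mean fractions 0.5/0.3/0.2.
  Per-patient fractions are Dirichlet-jittered around the means
  (concentration 12), which is what gives the habitat-2 volume fraction
  patient-to-patient variance.
- **Boundary realism.** Phenotype means ramp smoothly over ~3 mm at
  subregion interfaces, and outside the lesion the mean decays from the
  nearest rim value to background (90 units) over the 3 mm halo width — an
  intensity-gradient halo rather than a hard step, as on real contrast
  images where tissue classes blend at interfaces.
- **Bias field and noise.** A multiplicative field `1 + a·g/max|g|` with
  `g` Gaussian-smoothed white noise at 40 mm correlation length, amplitude
  `a = 0.2`; unit white acquisition noise; intensities floored at 1 so the
  log-domain correction is well defined. The true field is stored per
  patient for oracle tests.
- **Clinical table and response.** Covariates mimic an advanced-NSCLC
  cohort (age ~ N(64, 8), 67% male, blood counts and tumor markers with
  log-normal tails, PNI/SIRI derived from albumin and differential counts).
  The binary response is logistic in centered covariates with log-odds
  {habitat-2 volume fraction: +20, male gender: −0.8, PNI: +0.08 per unit};
  the intercept is calibrated by bisection so the mean predicted
  probability equals the target prevalence 0.46. The imaging coefficient is
  set so the volume-fraction oracle discriminates at AUC ≈ 0.88 and the
  clinical branch at ≈ 0.6–0.65, mirroring the discrimination levels this
  kind of habitat/clinical model reaches on real cohorts; these are
  generator conditions, fixed once.

What the generator does **not** emulate: anatomy (no brain structures,
skull, ventricles), multi-lesion patients (one dominant lesion each; the
dominant-lesion rule is exercised on constructed mask lists), scanner-to-
scanner distribution shift, motion/ghosting artifacts, and any coupling
between texture and response beyond the volume-fraction channel. Passing
tests therefore demonstrate that the pipeline recovers structure it is
pointed at under controlled conditions — not that the same AUCs would be
reached on patients.

## Preprocessing

Bias correction follows the log-domain multiplicative model: the log field
is estimated by heavy Gaussian smoothing (σ = spline_spacing/2, default
25 mm) of the log image via normalized convolution, with lesion voxels
excluded from the estimate and the field interpolated smoothly across them;
the field is normalized to geometric mean 1, so a bias-free image passes
through unchanged. Excluding the lesion matters at desk scale: a 2–3 cm
high-contrast lesion in a ~5 cm field of view is itself the dominant
low-frequency structure, and an unmasked estimator (including SimpleITK's
N4, available via `method="n4"`) absorbs lesion contrast into the field
(recovery correlation ~0.2–0.4 versus ≥ 0.97 for the masked estimator on
the generator's known fields). On whole-head images with a small lesion the
two approaches converge.

Resampling: 3rd-order B-spline for images, nearest-neighbour for masks
(keeps masks binary); target 1 mm isotropic. ICC is the two-way random,
absolute-agreement, single-measure form ICC(2,1), computed from the ANOVA
mean squares; an optional feature-reproducibility filter drops features
with between-rater ICC < 0.75.

## Habitat discovery

The 19 per-voxel channels are first-order statistics of the full 5×5×5
neighbourhood (windows truncated only at image borders): mean, median, SD,
variance, min, max, range, P10/P25/P75/P90, skewness, excess kurtosis,
energy (mean square), 32-bin entropy, uniformity, mean absolute deviation,
RMS, and mean gradient magnitude. Clustering is population-level: voxels
are pooled across training patients (default 1,000–2,000 per patient,
seeded) so habitat labels are comparable across patients; channels are
standardized by the training mean/SD, zero-variance channels dropped with a
warning. `k*` is chosen by mean rank of the three validity indices
(Silhouette and Calinski–Harabasz maximized, Davies–Bouldin minimized),
ties to the smaller k. K-means uses k-means++ with `n_seeds` restarts; the
best-inertia centers are frozen. Consistency is the mean over seed pairs of
voxel agreement after Hungarian matching of the k×k contingency table, so
it is invariant to label permutation. Assignment of new patients is
nearest-center in the frozen standardized space, ties to the lowest label.

**Known limitation.** With three phenotypes at brain-metastasis scale,
30–40% of voxels sit within a window radius of a subregion or lesion
boundary; their windows blend two tissue classes and light up the
dispersion channels, so K-means can prefer a boundary/texture partition
over the phenotype partition. Voxel-level truth recovery then plateaus
around 0.6–0.9 depending on geometry, even though k-selection (k* = 3) and
seed-to-seed consistency (> 99%) remain robust. The recovery test therefore
uses a two-phenotype separable configuration (single internal boundary),
where accuracy is 0.94–0.98.

## Regions and radiomics

Rings are `{0 < EDT ≤ r}` in physical mm (voxel-center convention); at 1 mm
spacing this undershoots the analytic shell volume of small spheres by
~20–24% (the digital surface lies inside the analytic one), converging as
spacing shrinks — tests pin these values.

The extractor follows the IBSI taxonomy. Discretization is fixed-bin-width
(default 25, relative to the region minimum); texture matrices are 3-D:
GLCM symmetric over the 13 unique directions (features averaged across
directions), GLRLM over the same 13 directions, GLSZM zones and GLDM
dependencies 26-connected, NGTDM over the 26-neighbourhood; logs are base
2. Shape uses the sharp marching-cubes mesh of the binary mask (volume by
divergence theorem, principal axes from the voxel-coordinate covariance,
2-D diameters from mesh-vertex projections). Two discretization facts are
frozen in tests rather than idealized: the mesh bevels 90° edges (a 10 mm
cube's surface area reads ~6% low) and staircase overestimates sphere area
(digitized-sphere sphericity ~0.90–0.91 at r = 5–6 mm). Intensity-transform
filters (square, square-root, logarithm, exponential) are rescaled to the
original intensity range so one bin width remains meaningful; wavelets are
single-level stationary (coif1) so sub-bands keep the grid shape; LoG uses
6 sigmas at 1–6 mm, which together with the other types makes the 20-type
bank whose 20 × 91 + 14 = 1,834 features match the printed inventory.

Regions smaller than 10 voxels are skipped (recorded); a missing habitat is
zero-imputed in the fused vector with its id recorded.

## Selection cascade

Stage order: significance → correlation → RFE → mRMR → LASSO; survivors are
strictly nested and all statistics use training rows only. Normality is
assessed per feature per class (Shapiro–Wilk at 0.05) choosing Welch's
t-test vs Mann–Whitney U. Correlation pruning is greedy on the largest
offending pair, dropping the member with the larger mean |r| to all
remaining features. RFE uses a seeded standardized logistic estimator
(default target 100 when more survive; the paper-scale intermediate counts
are configurable since no canonical values exist). mRMR is the difference
variant with F-statistic relevance normalized to [0, 1] (sharing the scale
of the |r| redundancy term) and a near-duplicate guard (|r| ≥ 0.99
candidates are deferred). LASSO is L1 logistic over a 30-point C grid with
stratified CV (deviance scoring, λ-min default, 1-SE optional); an empty
survivor set raises the no-signal flag and the caller falls back to the
mRMR set.

## Models and evaluation

Six algorithm families with small seeded CV grids (tree depth {2,3,4} or
{3,5,None}, 100/300 estimators, C grids for the linear/kernel models; SVM
probabilities via Platt-style calibration). Prediction never refits and
never imputes; missing columns raise. The combined signature is
feature-level concatenation of habitat survivors, optimal-ring survivors
and significant clinical covariates.

AUC is Mann–Whitney concordance with 0.5 tie credit; variance and the
paired two-model test use DeLong structural components. Operating
thresholds are Youden-optimal on training and frozen elsewhere.
Hosmer–Lemeshow uses decile-of-risk grouping (g = 10, degenerate groups
merged, p from χ²(g−2) as appropriate for fitted models; with known
probabilities the statistic is χ²(g), which the calibration test uses).
Decision curves use the 0.01–0.99 grid at 0.01 steps. Shapley attributions
are exact for linear models (on the logit scale) and tree ensembles (native
path-dependent contributions, float32, local accuracy ~1e−6) and seeded
permutation sampling otherwise (probability scale). The nomogram maps a
logistic model to points linear in coefficient × value, referenced at each
predictor's least-risk range end, scaled so the largest span is 100 points;
the inverse-logit round trip is exact to 1e−6.

## Problem sizes

The shipped experiments run at desk scale, chosen as the package's own
defaults: 60-patient cohorts for end-to-end runs (42/18 split), 8–12
patients for habitat-selection checks with ≤ 3,000 pooled voxels × 10
seeds × k = 3..10, the full 1,834-feature bank on single lesions and the
reduced single-type bank (105 features/region) for batch extraction, 2,000
replicates/features for the type-I-error calibrations, and 10 seeded
split/model replicates for the habitat-versus-background comparison (one
image cohort reused across replicates). Larger cohorts only sharpen the
same comparisons.
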
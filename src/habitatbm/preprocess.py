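"""Image normalization: bias-field correction, isotropic resampling,
dominant-lesion selection, and observer-agreement ICC.

Bias correction follows the N4 log-domain scheme (SimpleITK); the corrected
image equals the input divided voxelwise by the estimated smooth
multiplicative field.  Resampling brings image and mask to a 1x1x1 mm grid
(3rd-order B-spline for the image, nearest-neighbour for the mask, which
keeps masks binary).  ICC is the two-way random, absolute-agreement,
single-measure form ICC(2,1).
"""

from __future__ import annotations

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .core import LabelMask, Volume

__all__ = [
    "correct_bias",
    "resample_isotropic",
    "select_dominant_lesion",
    "icc_agreement",
    "icc_feature_filter",
]


def correct_bias(
    volume: Volume,
    mask: LabelMask | None = None,
    n_levels: int = 4,
    spline_spacing_mm: float = 50.0,
    method: str = "gaussian",
    shrink_factor: int = 2,
    on_nonpositive: str = "error",
) -> tuple[Volume, Volume]:
    """Log-domain multiplicative bias-field correction.

    Returns ``(corrected, bias_field)`` with ``corrected = volume / field``
    elementwise; the field is smooth (no energy above the ``spline_spacing_mm``
    scale) and normalized to geometric mean 1, so a bias-free image is
    unchanged.

    ``method="gaussian"`` (default) estimates the log field by heavy
    Gaussian smoothing (sigma = spline_spacing_mm / 2) of the log image via
    normalized convolution.  When ``mask`` marks a lesion, lesion voxels are
    excluded from the estimation (their high-contrast structure would
    otherwise be absorbed into the field) and the field is interpolated
    smoothly across them.  ``method="n4"`` runs SimpleITK's N4 scheme with
    ``n_levels`` multi-resolution levels; note that on small fields of view
    where the lesion dominates, N4 absorbs lesion contrast into the field.

    ``on_nonpositive`` controls handling of non-positive intensities (the
    method operates on log intensities): ``"error"`` raises, ``"shift"``
    adds a constant so the minimum is 1 before correcting.
    """
    vals = volume.values
    offset = 0.0
    if vals.min() <= 0:
        if on_nonpositive == "shift":
            offset = 1.0 - vals.min()
        else:
            raise ValueError(
                "volume contains non-positive intensities; pass on_nonpositive='shift'"
            )
    shifted = vals + offset
    if method == "gaussian":
        log_img = np.log(shifted)
        w = np.ones_like(log_img)
        if mask is not None:
            w[mask.bool_array()] = 0.0
        sigma_vox = [0.5 * spline_spacing_mm / s for s in volume.spacing]
        num = ndimage.gaussian_filter(log_img * w, sigma=sigma_vox, mode="constant")
        den = ndimage.gaussian_filter(w, sigma=sigma_vox, mode="constant")
        log_field = num / np.maximum(den, 1e-12)
        log_field -= log_field.mean()  # geometric mean 1
        field = np.exp(log_field)
    elif method == "n4":
        field = _n4_field(volume.with_values(shifted), n_levels, shrink_factor)
    else:
        raise ValueError("method must be 'gaussian' or 'n4'")
    corrected = shifted / field - offset
    return volume.with_values(corrected), volume.with_values(field)


def _n4_field(volume: Volume, n_levels: int, shrink_factor: int) -> np.ndarray:
    img = sitk.Cast(volume.to_sitk(), sitk.sitkFloat32)
    shrink = max(int(shrink_factor), 1)
    small = sitk.Shrink(img, [shrink] * 3) if shrink > 1 else img
    n4 = sitk.N4BiasFieldCorrectionImageFilter()
    n4.SetMaximumNumberOfIterations([50] * max(int(n_levels), 1))
    n4.Execute(small)
    log_field = n4.GetLogBiasFieldAsImage(img)  # full-resolution field
    return np.exp(Volume.from_sitk(log_field).values)


def resample_isotropic(
    volume: Volume, mask: LabelMask, target_mm: float = 1.0
) -> tuple[Volume, LabelMask]:
    """Resample image and mask to an isotropic ``target_mm`` grid.

    Image uses 3rd-order B-spline interpolation, mask nearest-neighbour so it
    stays binary; physical extent is preserved to within one voxel.
    """
    if not volume.same_geometry(mask):
        raise ValueError("volume and mask grids are not aligned")
    if target_mm <= 0:
        raise ValueError("target_mm must be > 0")
    img = volume.to_sitk()
    new_spacing = (target_mm,) * 3
    new_size = [
        max(1, int(round(sz * sp / target_mm)))
        for sz, sp in zip(img.GetSize(), img.GetSpacing())
    ]
    resampler = sitk.ResampleImageFilter()
    resampler.SetOutputSpacing(new_spacing)
    resampler.SetSize(new_size)
    resampler.SetOutputOrigin(img.GetOrigin())
    resampler.SetOutputDirection(img.GetDirection())
    resampler.SetInterpolator(sitk.sitkBSpline)
    out_img = Volume.from_sitk(resampler.Execute(img))

    resampler.SetInterpolator(sitk.sitkNearestNeighbor)
    out_mask = LabelMask.from_sitk(resampler.Execute(mask.to_sitk()))
    if out_mask.n_voxels == 0:
        raise ValueError("mask empty after resampling (lesion too small for target spacing)")
    return out_img, out_mask


def select_dominant_lesion(masks: list[LabelMask]) -> LabelMask:
    """Return the lesion mask with the largest physical volume.

    Ties are broken deterministically by the lexicographically smallest
    centroid coordinate (in physical mm) of the mask's nonzero voxels.
    """
    if not masks:
        raise ValueError("no masks given")
    candidates = [m for m in masks if m.n_voxels > 0]
    if not candidates:
        raise ValueError("all masks are empty")

    def key(m: LabelMask):
        idx = np.argwhere(m.bool_array())
        centroid = tuple((idx.mean(axis=0) * np.asarray(m.spacing)) + np.asarray(m.origin))
        return (-m.volume_mm3, centroid)

    return min(candidates, key=key)


def icc_agreement(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is an (n_subjects, n_raters) matrix with no missing cells.
    Computed from the two-way ANOVA mean squares:

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)

    with MS_R rows (subjects), MS_C columns (raters), MS_E residual.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D (subjects x raters) matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings contain missing or non-finite cells")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    if abs(ms_r) < 1e-15 and abs(denom) < 1e-15:
        raise ValueError("zero between-subject variance: ICC undefined")
    return float((ms_r - ms_e) / denom)


def icc_feature_filter(
    features_a: "np.ndarray | object",
    features_b: "np.ndarray | object",
    threshold: float = 0.75,
) -> list[int] | list[str]:
    """Reproducibility filter: keep features whose between-rater ICC(2,1)
    meets ``threshold``.

    ``features_a``/``features_b`` are (patients x features) arrays or
    DataFrames from the two raters' segmentations.  Returns the surviving
    column indices (or names for DataFrames).
    """
    import pandas as pd

    names = None
    if isinstance(features_a, pd.DataFrame):
        names = list(features_a.columns)
        a = features_a.to_numpy(dtype=float)
        b = features_b[names].to_numpy(dtype=float)
    else:
        a = np.asarray(features_a, dtype=float)
        b = np.asarray(features_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("rater feature matrices must have identical shape")
    keep = []
    for j in range(a.shape[1]):
        col = np.column_stack([a[:, j], b[:, j]])
        try:
            icc = icc_agreement(col)
        except ValueError:
            continue
        if icc >= threshold:
            keep.append(names[j] if names is not None else j)
    return keep
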
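"""Region-level radiomic feature extraction.

Feature vectors follow the IBSI taxonomy: 14 shape descriptors computed once
per region from the binary mask, and 91 intensity/texture features (18
first-order + 22 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM + 5 NGTDM) computed on
every configured image type.  With the default 20-type filter bank this
yields 14 + 20 x 91 = 1,834 features per region, of which 360 are
first-order; fusing k=3 habitat regions gives 3 x 1,834 = 5,502 columns.

Column names are ``filter__family__feature`` (``shape__...`` for shape), and
``region__filter__family__feature`` once tagged with a region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

from .core import LabelMask, Volume
from .imagefilters import default_image_types, filter_bank
from .regions import RegionSet
from .texture import texture_features

__all__ = [
    "FeatureConfig",
    "discretize",
    "firstorder_features",
    "shape_features",
    "extract_region_features",
    "extract_patient_features",
    "fuse_habitat_features",
    "build_feature_table",
]

_EPS = np.spacing(1.0)


@dataclass
class FeatureConfig:
    """Extraction configuration.

    ``bin_width`` is the fixed bin width for gray-level discretization
    (applied per region, relative to the region minimum).  ``image_types``
    defaults to the 20-type bank; ``minimal`` offers a cheap single-type
    configuration for large batch runs.
    """

    image_types: list[str] = field(default_factory=default_image_types)
    bin_width: float = 25.0
    bin_count: int | None = None  # overrides bin_width when set
    max_levels: int = 512
    shape_enabled: bool = True
    min_voxels: int = 10

    @classmethod
    def minimal(cls, **kw) -> "FeatureConfig":
        return cls(image_types=["original"], **kw)

    @property
    def n_features(self) -> int:
        per_type = 18 + 22 + 16 + 16 + 14 + 5
        return (14 if self.shape_enabled else 0) + len(self.image_types) * per_type


def discretize(
    intensities: np.ndarray,
    bin_width: float | None = 25.0,
    bin_count: int | None = None,
) -> np.ndarray:
    """Map region intensities to integer gray levels >= 1.

    Fixed-bin-width (default): ``level = floor((x - min) / w) + 1``.  With
    ``bin_count`` set, a fixed number of equal-width bins over the region
    range is used instead.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise ValueError("empty region")
    lo = x.min()
    if bin_count is not None:
        if bin_count < 1:
            raise ValueError("bin_count must be >= 1")
        rng = x.max() - lo
        if rng <= 0:
            return np.ones_like(x, dtype=np.int64)
        lev = np.floor((x - lo) / rng * bin_count).astype(np.int64) + 1
        return np.minimum(lev, bin_count)
    if bin_width is None or bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    lev = np.floor((x - lo) / bin_width).astype(np.int64) + 1
    return lev


def firstorder_features(x: np.ndarray, voxel_volume: float, bin_width: float,
                        bin_count: int | None = None) -> dict[str, float]:
    """The 18 first-order statistics of region intensities."""
    x = np.asarray(x, dtype=float)
    n = x.size
    mean = x.mean()
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    var = x.var()
    energy = float((x**2).sum())
    levels = discretize(x, bin_width, bin_count)
    p = np.bincount(levels)[1:] / n
    nz = p[p > 0]
    sel = (x >= p10) & (x <= p90)
    xr = x[sel]
    m2 = var
    if m2 > 1e-24:
        skew = float(((x - mean) ** 3).mean() / m2**1.5)
        kurt = float(((x - mean) ** 4).mean() / m2**2)
    else:
        skew, kurt = 0.0, 0.0
    return {
        "Energy": energy,
        "TotalEnergy": energy * voxel_volume,
        "Entropy": float(-(nz * np.log2(nz)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(xr - xr.mean()).mean())
        if xr.size
        else 0.0,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": float(var),
        "Uniformity": float((p**2).sum()),
    }


def _mesh(mask_arr: np.ndarray, spacing):
    padded = np.pad(mask_arr.astype(float), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    return verts, faces


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    tri = verts[faces]
    cross = np.cross(tri[:, 1], tri[:, 2])
    return float(abs((tri[:, 0] * cross).sum() / 6.0))


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 400:
        try:
            hull = ConvexHull(points)
            points = points[hull.vertices]
        except Exception:  # degenerate (coplanar) point sets
            pass
    return float(pdist(points).max())


def shape_features(mask: LabelMask) -> dict[str, float]:
    """The 14 mesh- and moment-based shape descriptors (mm units)."""
    m = mask.bool_array()
    if not m.any():
        raise ValueError("empty mask")
    sp = np.asarray(mask.spacing)
    verts, faces = _mesh(m, sp)
    mesh_v = _mesh_volume(verts, faces)
    sa = float(measure.mesh_surface_area(verts, faces))
    voxel_v = mask.volume_mm3

    coords = np.argwhere(m) * sp
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.maximum(eig, 0.0)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()

    hull_pts = verts  # mesh vertices, physical mm
    max3d = _max_pairwise(hull_pts)
    # 2-D diameters: max pairwise distance in each orthogonal projection.
    d_slice = _max_pairwise(hull_pts[:, :2])   # in-plane (axes 0,1)
    d_col = _max_pairwise(hull_pts[:, [0, 2]])
    d_row = _max_pairwise(hull_pts[:, 1:])
    sphericity = float((36.0 * np.pi * mesh_v**2) ** (1.0 / 3.0) / sa) if sa > 0 else 0.0
    return {
        "MeshVolume": mesh_v,
        "VoxelVolume": voxel_v,
        "SurfaceArea": sa,
        "SurfaceVolumeRatio": sa / mesh_v if mesh_v > 0 else 0.0,
        "Sphericity": sphericity,
        "Maximum3DDiameter": max3d,
        "Maximum2DDiameterSlice": d_slice,
        "Maximum2DDiameterColumn": d_col,
        "Maximum2DDiameterRow": d_row,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0,
        "Flatness": float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0,
    }


def _crop_for_region(volume: Volume, masks: list[np.ndarray], margin: int = 7):
    union = np.zeros(volume.shape, dtype=bool)
    for m in masks:
        union |= m
    idx = np.argwhere(union)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + margin, np.array(volume.shape))
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return sl


def _region_vector(
    bank: dict[str, np.ndarray],
    mask_crop: np.ndarray,
    mask: LabelMask,
    config: FeatureConfig,
) -> dict[str, float]:
    out: dict[str, float] = {}
    if config.shape_enabled:
        for name, val in shape_features(mask).items():
            out[f"shape__{name}"] = val
    voxel_v = mask.voxel_volume_mm3
    for ftype in config.image_types:
        img = bank[ftype]
        x = img[mask_crop]
        for name, val in firstorder_features(x, voxel_v, config.bin_width, config.bin_count).items():
            out[f"{ftype}__firstorder__{name}"] = val
        lev_vals = discretize(x, config.bin_width, config.bin_count)
        if lev_vals.max() > config.max_levels:
            warnings.warn(
                f"{ftype}: {lev_vals.max()} gray levels exceed max_levels; "
                f"falling back to {64} fixed bins for texture"
            )
            lev_vals = discretize(x, bin_count=64)
        levels = np.zeros(img.shape, dtype=np.int64)
        levels[mask_crop] = lev_vals
        for name, val in texture_features(levels).items():
            out[f"{ftype}__{name}"] = val
    return out


def extract_region_features(
    volume: Volume, mask: LabelMask, config: FeatureConfig | None = None
) -> dict[str, float] | None:
    """Full feature vector for one region; ``None`` when the region is below
    ``config.min_voxels`` (reason recorded via warning)."""
    config = config or FeatureConfig()
    if not volume.same_geometry(mask):
        raise ValueError("volume and mask grids are not aligned")
    if mask.n_voxels < config.min_voxels:
        warnings.warn(
            f"region has {mask.n_voxels} voxels (< {config.min_voxels}); skipped"
        )
        return None
    m = mask.bool_array()
    sl = _crop_for_region(volume, [m])
    bank = filter_bank(volume.values[sl], volume.spacing, config.image_types)
    return _region_vector(bank, m[sl], mask, config)


def extract_patient_features(
    volume: Volume, region_set: RegionSet, config: FeatureConfig | None = None
) -> dict[str, dict[str, float] | None]:
    """Feature vectors for every region of a patient.

    The filter bank is computed once on the union bounding box and shared by
    all regions (tumor, rings, habitats).
    """
    config = config or FeatureConfig()
    regions = region_set.all_regions()
    arrays = [m.bool_array() for m in regions.values()]
    sl = _crop_for_region(volume, arrays)
    bank = filter_bank(volume.values[sl], volume.spacing, config.image_types)
    out: dict[str, dict[str, float] | None] = {}
    for name, mask in regions.items():
        if mask.n_voxels < config.min_voxels:
            warnings.warn(f"region {name}: {mask.n_voxels} voxels; skipped")
            out[name] = None
            continue
        out[name] = _region_vector(bank, mask.bool_array()[sl], mask, config)
    return out


def fuse_habitat_features(
    per_habitat: dict[int, dict[str, float] | None], k: int = 3
) -> tuple[dict[str, float], list[int]]:
    """Early fusion: concatenate per-habitat vectors with habitat-id prefixes.

    Missing habitats are imputed with zeros; the returned list records which
    habitat ids were missing.  For k=3 and the default config the fused
    vector has 5,502 entries.
    """
    names = None
    for vec in per_habitat.values():
        if vec is not None:
            if names is None:
                names = list(vec.keys())
            elif list(vec.keys()) != names:
                raise ValueError("inconsistent per-habitat feature name sets")
    if names is None:
        raise ValueError("all habitat vectors are missing")
    fused: dict[str, float] = {}
    missing: list[int] = []
    for h in range(1, k + 1):
        vec = per_habitat.get(h)
        if vec is None:
            missing.append(h)
            for n in names:
                fused[f"habitat{h}__{n}"] = 0.0
        else:
            for n, v in vec.items():
                fused[f"habitat{h}__{n}"] = v
    return fused, missing


def build_feature_table(rows: list[dict[str, float]], index: list[str] | None = None) -> pd.DataFrame:
    """Assemble per-patient feature dicts into a patients x features table."""
    df = pd.DataFrame(rows, index=index)
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature columns: {dup[:5]}")
    return df
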
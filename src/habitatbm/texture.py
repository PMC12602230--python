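"""Gray-level texture matrices and their derived features.

All matrices operate on a discretized level grid (integer levels 1..Ng on
region voxels, 0 elsewhere) and follow the standard 3-D definitions: GLCM
and GLRLM aggregate over the 13 unique 3-D directions (features averaged
across directions), GLSZM zones and GLDM dependencies use 26-connectivity,
and NGTDM uses the 26-neighbourhood gray-tone difference.  Logarithms are
base 2.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "DIRECTIONS_13",
    "glcm_matrix",
    "glrlm_matrix",
    "glszm_matrix",
    "gldm_matrix",
    "ngtdm_table",
    "texture_matrices",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
    "texture_features",
]

_EPS = np.spacing(1.0)


def _unique_directions() -> list[tuple[int, int, int]]:
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                if d > (0, 0, 0):  # lexicographic half of the 26 neighbours
                    dirs.append(d)
    return dirs


#: The 13 unique 3-D co-occurrence / run directions (distance 1).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(_unique_directions())

_OFFSETS_26 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)


def _check_levels(levels: np.ndarray) -> int:
    levels = np.asarray(levels)
    if not np.issubdtype(levels.dtype, np.integer):
        raise ValueError("levels must be an integer grid (0 outside the region)")
    ng = int(levels.max())
    if ng < 1:
        raise ValueError("empty region: no positive levels")
    return ng


def _shifted_pairs(levels: np.ndarray, offset):
    """Index slices pairing each voxel with its offset neighbour."""
    sl_a, sl_b = [], []
    for d, n in zip(offset, levels.shape):
        if d == 0:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
        elif d > 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    return tuple(sl_a), tuple(sl_b)


def glcm_matrix(
    levels: np.ndarray, symmetric: bool = True,
    directions=DIRECTIONS_13,
) -> np.ndarray:
    """Co-occurrence counts, shape (Ng, Ng, n_directions).

    Counts pairs of in-region voxels at distance 1 along each direction;
    symmetric GLCMs count each pair in both orders.
    """
    ng = _check_levels(levels)
    out = np.zeros((ng, ng, len(directions)))
    for di, d in enumerate(directions):
        sa, sb = _shifted_pairs(levels, d)
        a = levels[sa].ravel()
        b = levels[sb].ravel()
        ok = (a > 0) & (b > 0)
        np.add.at(out[:, :, di], (a[ok] - 1, b[ok] - 1), 1)
        if symmetric:
            np.add.at(out[:, :, di], (b[ok] - 1, a[ok] - 1), 1)
    return out


def glrlm_matrix(levels: np.ndarray, directions=DIRECTIONS_13) -> np.ndarray:
    """Run-length counts, shape (Ng, max_run_length, n_directions)."""
    ng = _check_levels(levels)
    max_len = int(np.ceil(np.sqrt(3) * max(levels.shape))) + 1
    out = np.zeros((ng, max_len, len(directions)))
    region = levels > 0
    idx_all = np.argwhere(region)
    shape = np.array(levels.shape)
    for di, d in enumerate(directions):
        d = np.array(d)
        # Run starts: region voxels whose predecessor along d is outside the
        # grid, outside the region, or a different level.
        prev = idx_all - d
        inside = np.all((prev >= 0) & (prev < shape), axis=1)
        same = np.zeros(len(idx_all), dtype=bool)
        pi = prev[inside]
        same[inside] = levels[tuple(pi.T)] == levels[tuple(idx_all[inside].T)]
        starts = idx_all[~same]
        if starts.size == 0:
            continue
        lev = levels[tuple(starts.T)]
        cur = starts
        length = np.ones(len(starts), dtype=np.int64)
        active = np.arange(len(starts))
        while active.size:
            nxt = cur + d
            ok = np.all((nxt >= 0) & (nxt < shape), axis=1)
            cont = np.zeros(len(cur), dtype=bool)
            ni = nxt[ok]
            cont[ok] = levels[tuple(ni.T)] == lev[active][ok] * 1
            # record finished runs
            done = ~cont
            np.add.at(out[:, :, di], (lev[active[done]] - 1, length[done] - 1), 1)
            cur = nxt[cont]
            length = length[cont] + 1
            active = active[cont]
    return out


def glszm_matrix(levels: np.ndarray) -> np.ndarray:
    """Size-zone counts, shape (Ng, max_zone_size); zones are 26-connected."""
    ng = _check_levels(levels)
    structure = np.ones((3, 3, 3), dtype=int)
    zones: list[tuple[int, int]] = []
    max_size = 1
    for g in range(1, ng + 1):
        lab, n = ndimage.label(levels == g, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            zones.append((g, int(s)))
            max_size = max(max_size, int(s))
    out = np.zeros((ng, max_size))
    for g, s in zones:
        out[g - 1, s - 1] += 1
    return out


def gldm_matrix(levels: np.ndarray, alpha: int = 0) -> np.ndarray:
    """Dependence counts, shape (Ng, 27).

    A neighbour is dependent when it is in the region and its level differs
    from the centre's by at most ``alpha``; column j holds dependence count
    j (0..26 neighbours).
    """
    ng = _check_levels(levels)
    region = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for d in _OFFSETS_26:
        sa, sb = _shifted_pairs(levels, d)
        ok = region[sa] & region[sb] & (np.abs(levels[sa] - levels[sb]) <= alpha)
        dep[sa] += ok
    out = np.zeros((ng, 27))
    lv = levels[region] - 1
    dv = dep[region]
    np.add.at(out, (lv, dv), 1)
    return out


def ngtdm_table(levels: np.ndarray) -> np.ndarray:
    """NGTDM: rows are levels 1..Ng, columns (n_i, p_i, s_i).

    s_i sums |i - A| over region voxels of level i, where A is the mean
    level of the voxel's in-region 26-neighbours; voxels with no in-region
    neighbour contribute 0 to s but count in n.
    """
    ng = _check_levels(levels)
    region = levels > 0
    ssum = np.zeros(levels.shape)
    cnt = np.zeros(levels.shape)
    for d in _OFFSETS_26:
        sa, sb = _shifted_pairs(levels, d)
        contrib = np.where(region[sb], levels[sb], 0)
        ssum[sa] += np.where(region[sa], contrib, 0)
        cnt[sa] += region[sa] & region[sb]
    with np.errstate(invalid="ignore", divide="ignore"):
        abar = np.where(cnt > 0, ssum / np.maximum(cnt, 1), 0.0)
    diff = np.where((cnt > 0) & region, np.abs(levels - abar), 0.0)
    n_p = float(region.sum())
    out = np.zeros((ng, 3))
    for g in range(1, ng + 1):
        sel = levels == g
        out[g - 1, 0] = sel.sum()
        out[g - 1, 2] = diff[sel].sum()
    out[:, 1] = out[:, 0] / n_p
    return out


def texture_matrices(levels: np.ndarray) -> dict[str, np.ndarray]:
    """All five texture matrices for a discretized region grid."""
    return {
        "glcm": glcm_matrix(levels),
        "glrlm": glrlm_matrix(levels),
        "glszm": glszm_matrix(levels),
        "gldm": gldm_matrix(levels),
        "ngtdm": ngtdm_table(levels),
    }


# --------------------------------------------------------------------------
# Feature families


def _xlogx(p: np.ndarray) -> np.ndarray:
    return np.where(p > 0, p * np.log2(p + _EPS), 0.0)


def glcm_features(counts: np.ndarray) -> dict[str, float]:
    """22 GLCM features, averaged over directions."""
    ng = counts.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    per_dir: list[dict[str, float]] = []
    for di in range(counts.shape[2]):
        C = counts[:, :, di]
        total = C.sum()
        if total == 0:
            continue
        p = C / total
        px = p.sum(axis=1)
        py = p.sum(axis=0)
        mux = float((i * px).sum())
        muy = float((i * py).sum())
        sigx = np.sqrt(((i - mux) ** 2 * px).sum())
        sigy = np.sqrt(((i - muy) ** 2 * py).sum())
        # diagonal (difference) and cross (sum) distributions
        k_diff = np.arange(ng)
        p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
        k_sum = np.arange(2, 2 * ng + 1)
        p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])
        hx = -_xlogx(px).sum()
        hy = -_xlogx(py).sum()
        hxy = -_xlogx(p).sum()
        pxpy = np.outer(px, py)
        hxy1 = -(p * np.log2(pxpy + _EPS) * (p > 0)).sum()
        hxy2 = -_xlogx(pxpy).sum()
        da = float((k_diff * p_diff).sum())
        corr_den = sigx * sigy
        d: dict[str, float] = {
            "Autocorrelation": float((ii * jj * p).sum()),
            "JointAverage": mux,
            "ClusterProminence": float(((ii + jj - mux - muy) ** 4 * p).sum()),
            "ClusterShade": float(((ii + jj - mux - muy) ** 3 * p).sum()),
            "ClusterTendency": float(((ii + jj - mux - muy) ** 2 * p).sum()),
            "Contrast": float(((ii - jj) ** 2 * p).sum()),
            "Correlation": float(((ii * jj * p).sum() - mux * muy) / corr_den)
            if corr_den > 0
            else 1.0,
            "DifferenceAverage": da,
            "DifferenceEntropy": float(-_xlogx(p_diff).sum()),
            "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
            "JointEnergy": float((p**2).sum()),
            "JointEntropy": float(hxy),
            "Imc1": float((hxy - hxy1) / max(hx, hy)) if max(hx, hy) > 0 else 0.0,
            "Imc2": float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))),
            "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
            "Idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
            "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
            "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
            "InverseVariance": float(
                (p[ii != jj] / (ii - jj)[ii != jj] ** 2).sum()
            ),
            "MaximumProbability": float(p.max()),
            "SumEntropy": float(-_xlogx(p_sum).sum()),
            "SumSquares": float(((ii - mux) ** 2 * p).sum()),
        }
        per_dir.append(d)
    keys = per_dir[0].keys()
    return {k: float(np.mean([d[k] for d in per_dir])) for k in keys}


def _size_family(P: np.ndarray, n_voxels: float, prefix: dict[str, str]) -> dict[str, float]:
    """Shared feature formulas for GLRLM (runs) / GLSZM (zones) / GLDM.

    ``P`` is the (Ng, Ns) count matrix; ``prefix`` maps generic names to the
    family-specific feature names.
    """
    ng, ns = P.shape
    i = np.arange(1, ng + 1)[:, None]
    s = np.arange(1, ns + 1)[None, :]
    n = P.sum()
    if n == 0:
        return {v: 0.0 for v in prefix.values()}
    p = P / n
    mu_i = (p * i).sum()
    mu_s = (p * s).sum()
    vals = {
        "small": float((P / s**2).sum() / n),
        "large": float((P * s**2).sum() / n),
        "gln": float((P.sum(axis=1) ** 2).sum() / n),
        "glnn": float((P.sum(axis=1) ** 2).sum() / n**2),
        "sn": float((P.sum(axis=0) ** 2).sum() / n),
        "snn": float((P.sum(axis=0) ** 2).sum() / n**2),
        "percentage": float(n / n_voxels),
        "glv": float((p * (i - mu_i) ** 2).sum()),
        "sv": float((p * (s - mu_s) ** 2).sum()),
        "entropy": float(-_xlogx(p).sum()),
        "lgl": float((P / i**2).sum() / n),
        "hgl": float((P * i**2).sum() / n),
        "slgl": float((P / (i**2 * s**2)).sum() / n),
        "shgl": float((P * i**2 / s**2).sum() / n),
        "llgl": float((P * s**2 / i**2).sum() / n),
        "lhgl": float((P * i**2 * s**2).sum() / n),
    }
    return {name: vals[key] for key, name in prefix.items()}


_GLRLM_NAMES = {
    "small": "ShortRunEmphasis",
    "large": "LongRunEmphasis",
    "gln": "GrayLevelNonUniformity",
    "glnn": "GrayLevelNonUniformityNormalized",
    "sn": "RunLengthNonUniformity",
    "snn": "RunLengthNonUniformityNormalized",
    "percentage": "RunPercentage",
    "glv": "GrayLevelVariance",
    "sv": "RunVariance",
    "entropy": "RunEntropy",
    "lgl": "LowGrayLevelRunEmphasis",
    "hgl": "HighGrayLevelRunEmphasis",
    "slgl": "ShortRunLowGrayLevelEmphasis",
    "shgl": "ShortRunHighGrayLevelEmphasis",
    "llgl": "LongRunLowGrayLevelEmphasis",
    "lhgl": "LongRunHighGrayLevelEmphasis",
}

_GLSZM_NAMES = {
    "small": "SmallAreaEmphasis",
    "large": "LargeAreaEmphasis",
    "gln": "GrayLevelNonUniformity",
    "glnn": "GrayLevelNonUniformityNormalized",
    "sn": "SizeZoneNonUniformity",
    "snn": "SizeZoneNonUniformityNormalized",
    "percentage": "ZonePercentage",
    "glv": "GrayLevelVariance",
    "sv": "ZoneVariance",
    "entropy": "ZoneEntropy",
    "lgl": "LowGrayLevelZoneEmphasis",
    "hgl": "HighGrayLevelZoneEmphasis",
    "slgl": "SmallAreaLowGrayLevelEmphasis",
    "shgl": "SmallAreaHighGrayLevelEmphasis",
    "llgl": "LargeAreaLowGrayLevelEmphasis",
    "lhgl": "LargeAreaHighGrayLevelEmphasis",
}

# GLDM keeps 14 of the shared formulas (no percentage: every voxel has a
# dependence; no normalized size column beyond DNN).
_GLDM_NAMES = {
    "small": "SmallDependenceEmphasis",
    "large": "LargeDependenceEmphasis",
    "gln": "GrayLevelNonUniformity",
    "sn": "DependenceNonUniformity",
    "snn": "DependenceNonUniformityNormalized",
    "glv": "GrayLevelVariance",
    "sv": "DependenceVariance",
    "entropy": "DependenceEntropy",
    "lgl": "LowGrayLevelEmphasis",
    "hgl": "HighGrayLevelEmphasis",
    "slgl": "SmallDependenceLowGrayLevelEmphasis",
    "shgl": "SmallDependenceHighGrayLevelEmphasis",
    "llgl": "LargeDependenceLowGrayLevelEmphasis",
    "lhgl": "LargeDependenceHighGrayLevelEmphasis",
}


def glrlm_features(counts: np.ndarray, n_voxels: int) -> dict[str, float]:
    """16 GLRLM features, averaged over the 13 directions."""
    per_dir = []
    for di in range(counts.shape[2]):
        P = counts[:, :, di]
        if P.sum() == 0:
            continue
        per_dir.append(_size_family(P, n_voxels, _GLRLM_NAMES))
    keys = per_dir[0].keys()
    return {k: float(np.mean([d[k] for d in per_dir])) for k in keys}


def glszm_features(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    """16 GLSZM features."""
    return _size_family(P, n_voxels, _GLSZM_NAMES)


def gldm_features(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    """14 GLDM features (dependence column is count + 1)."""
    # shift dependence 0..26 -> size index 1..27 is already the column index
    return _size_family(P, n_voxels, _GLDM_NAMES)


def ngtdm_features(table: np.ndarray) -> dict[str, float]:
    """5 NGTDM features (Coarseness, Contrast, Busyness, Complexity, Strength)."""
    n_i = table[:, 0]
    p_i = table[:, 1]
    s_i = table[:, 2]
    ng_levels = np.arange(1, len(p_i) + 1, dtype=float)
    present = p_i > 0
    n_p = n_i.sum()
    ngp = int(present.sum())
    coarse_den = float((p_i * s_i).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6
    if ngp > 1:
        ii = ng_levels[present][:, None]
        jj = ng_levels[present][None, :]
        pi = p_i[present][:, None]
        pj = p_i[present][None, :]
        contrast = float(
            (pi * pj * (ii - jj) ** 2).sum() / (ngp * (ngp - 1)) * (s_i.sum() / n_p)
        )
        busy_den = float(np.abs(ii * pi - jj * pj).sum())
        busyness = float((p_i * s_i).sum() / busy_den) if busy_den > 0 else 0.0
        si = s_i[present][:, None]
        sj = s_i[present][None, :]
        complexity = float(
            (np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum() / n_p
        )
        s_total = float(s_i.sum())
        strength = float(((pi + pj) * (ii - jj) ** 2).sum() / s_total) if s_total > 0 else 0.0
    else:
        contrast = busyness = strength = 0.0
        complexity = 0.0
    return {
        "Coarseness": float(coarseness),
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


def texture_features(levels: np.ndarray) -> dict[str, float]:
    """All 73 texture features for one discretized region grid."""
    n_vox = int((levels > 0).sum())
    mats = texture_matrices(levels)
    out: dict[str, float] = {}
    for name, val in glcm_features(mats["glcm"]).items():
        out[f"glcm__{name}"] = val
    for name, val in glrlm_features(mats["glrlm"], n_vox).items():
        out[f"glrlm__{name}"] = val
    for name, val in glszm_features(mats["glszm"], n_vox).items():
        out[f"glszm__{name}"] = val
    for name, val in gldm_features(mats["gldm"], n_vox).items():
        out[f"gldm__{name}"] = val
    for name, val in ngtdm_features(mats["ngtdm"]).items():
        out[f"ngtdm__{name}"] = val
    return out
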
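"""Peritumoral ring construction and region bookkeeping.

Rings are built from the exact Euclidean distance transform in physical mm
(not voxel-structuring-element dilation), so a 1/2/3 mm radius is an honest
physical distance on any grid spacing.  A :class:`RegionSet` materializes the
tumor mask, the per-radius rings, and the per-habitat masks that partition
the tumor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import LabelMask

__all__ = ["RegionSet", "peritumoral_ring", "build_region_set"]


@dataclass
class RegionSet:
    """Tumor, peritumoral rings (radius mm -> mask) and habitat masks."""

    tumor: LabelMask
    rings: dict[float, LabelMask] = field(default_factory=dict)
    habitats: dict[int, LabelMask] = field(default_factory=dict)

    def all_regions(self) -> dict[str, LabelMask]:
        out = {"tumor": self.tumor}
        for r, m in sorted(self.rings.items()):
            out[f"peri{r:g}mm"] = m
        for h, m in sorted(self.habitats.items()):
            out[f"habitat{h}"] = m
        return out


def peritumoral_ring(
    tumor: LabelMask,
    radius_mm: float,
    brain_mask: LabelMask | None = None,
    exclude: LabelMask | None = None,
) -> LabelMask:
    """Voxels with Euclidean distance-to-tumor in (0, radius_mm].

    The ring is disjoint from the tumor by construction; when ``brain_mask``
    is given the ring is clipped to it, and ``exclude`` (e.g. other lesions)
    is removed.  ``radius_mm <= 0`` yields an empty ring with a warning.
    """
    t = tumor.bool_array()
    if not t.any():
        raise ValueError("tumor mask is empty")
    if radius_mm <= 0:
        warnings.warn("non-positive ring radius: returning an empty ring")
        return tumor.with_values(np.zeros_like(tumor.values))
    dist = ndimage.distance_transform_edt(~t, sampling=tumor.spacing)
    ring = (dist > 0) & (dist <= radius_mm)
    if brain_mask is not None:
        ring &= brain_mask.bool_array()
        if not ring.any():
            raise ValueError("ring empty after brain-mask clipping")
    if exclude is not None:
        ring &= ~exclude.bool_array()
    return tumor.with_values(ring.astype(np.int32))


def build_region_set(
    tumor: LabelMask,
    habitat_label_map: LabelMask | None = None,
    radii: tuple[float, ...] = (1.0, 2.0, 3.0),
    brain_mask: LabelMask | None = None,
) -> RegionSet:
    """Materialize tumor, per-radius rings and per-habitat masks.

    Habitat masks must partition the tumor exactly (every tumor voxel carries
    a habitat label).
    """
    t = tumor.bool_array()
    rings = {float(r): peritumoral_ring(tumor, float(r), brain_mask) for r in radii}
    habitats: dict[int, LabelMask] = {}
    if habitat_label_map is not None:
        if not tumor.same_geometry(habitat_label_map):
            raise ValueError("habitat map grid does not match tumor")
        hvals = habitat_label_map.values
        if np.any(t & (hvals == 0)):
            raise ValueError("habitat map does not cover every tumor voxel")
        for h in np.unique(hvals[t]):
            habitats[int(h)] = tumor.with_values(((hvals == h) & t).astype(np.int32))
    return RegionSet(tumor=tumor, rings=rings, habitats=habitats)
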
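"""Core spatial containers shared across the pipeline.

A :class:`Volume` is a 3-D scalar grid with physical geometry (spacing and
origin in mm); a :class:`LabelMask` is the integer-valued counterpart used
for ROIs, habitat label maps and peritumoral rings.  Arrays are indexed
``(i, j, k)`` with ``spacing[n]`` giving the physical step along axis ``n``;
conversion to/from SimpleITK (which stores arrays ``(z, y, x)``) reverses the
axis order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk

__all__ = ["Volume", "LabelMask", "read_volume", "read_mask"]


def _as_tuple3(x) -> tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ValueError(f"expected a length-3 triple, got {x!r}")
    return t  # type: ignore[return-value]


@dataclass
class Volume:
    """3-D scalar image with physical geometry.

    Parameters
    ----------
    values
        3-D floating-point array indexed ``(i, j, k)``.
    spacing
        Physical voxel size in mm per array axis; all entries must be > 0.
    origin
        Physical coordinate of voxel ``(0, 0, 0)`` in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("Volume values must be a 3-D array")
        self.spacing = _as_tuple3(self.spacing)
        self.origin = _as_tuple3(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Volume values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "Volume | LabelMask", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def with_values(self, values: np.ndarray) -> "Volume":
        return replace(self, values=np.asarray(values, dtype=np.float64))

    # ---- SimpleITK / NIfTI interop -------------------------------------
    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.values.transpose(2, 1, 0)))
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "Volume":
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return cls(arr.astype(np.float64), tuple(img.GetSpacing()), tuple(img.GetOrigin()))

    def save(self, path: str) -> None:
        sitk.WriteImage(self.to_sitk(), str(path))


@dataclass
class LabelMask:
    """Integer label grid aligned to a :class:`Volume`.

    Binary ROIs use values {0, 1}; habitat maps use 0 outside the lesion and
    1..k inside.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("LabelMask values must be a 3-D array")
        if not np.issubdtype(self.values.dtype, np.integer):
            v = np.asarray(self.values)
            if not np.allclose(v, np.round(v)):
                raise ValueError("LabelMask values must be integers")
            self.values = np.round(v).astype(np.int32)
        else:
            self.values = self.values.astype(np.int32)
        self.spacing = _as_tuple3(self.spacing)
        self.origin = _as_tuple3(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    shape = Volume.shape
    voxel_volume_mm3 = Volume.voxel_volume_mm3
    same_geometry = Volume.same_geometry

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(np.unique(self.values), (0, 1)).all())

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.values))

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3

    def bool_array(self) -> np.ndarray:
        return self.values > 0

    def with_values(self, values: np.ndarray) -> "LabelMask":
        return replace(self, values=np.asarray(values))

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(self.values.transpose(2, 1, 0).astype(np.uint16))
        )
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "LabelMask":
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return cls(arr.astype(np.int32), tuple(img.GetSpacing()), tuple(img.GetOrigin()))

    def save(self, path: str) -> None:
        sitk.WriteImage(self.to_sitk(), str(path))


def read_volume(path: str) -> Volume:
    """Read a NIfTI (or any SimpleITK-readable) scalar image."""
    return Volume.from_sitk(sitk.ReadImage(str(path), sitk.sitkFloat64))


def read_mask(path: str) -> LabelMask:
    """Read a NIfTI label image as a :class:`LabelMask`."""
    return LabelMask.from_sitk(sitk.ReadImage(str(path), sitk.sitkUInt16))
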
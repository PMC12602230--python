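"""Filter bank producing the derived image types for radiomic extraction.

Default inventory (20 types): the original image, 8 single-level stationary
3-D wavelet sub-bands (coif1; L/H per axis), Laplacian-of-Gaussian at 6
sigmas (1-6 mm), four intensity transforms (square, square-root, logarithm,
exponential, each rescaled to the original intensity range so a shared bin
width stays meaningful), and the gradient-magnitude image.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage

__all__ = ["default_image_types", "apply_filter", "filter_bank"]

LOG_SIGMAS_MM = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
WAVELET_NAME = "coif1"
_WAVELET_BANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


def default_image_types() -> list[str]:
    """Names of the 20 default image types, in extraction order."""
    types = ["original"]
    types += [f"wavelet-{b}" for b in _WAVELET_BANDS]
    types += [f"log-sigma-{s:g}mm" for s in LOG_SIGMAS_MM]
    types += ["square", "squareroot", "logarithm", "exponential", "gradient"]
    return types


def _wavelet_bands(values: np.ndarray) -> dict[str, np.ndarray]:
    # swt needs even extents: pad symmetrically, crop back.
    pads = [(0, s % 2) for s in values.shape]
    padded = np.pad(values, pads, mode="symmetric")
    coeffs = pywt.swtn(padded, WAVELET_NAME, level=1, start_level=0)[0]
    out = {}
    for key, arr in coeffs.items():  # key like 'ada' per axis: a=low, d=high
        band = "".join("L" if c == "a" else "H" for c in key)
        crop = tuple(slice(0, s) for s in values.shape)
        out[f"wavelet-{band}"] = arr[crop]
    return out


def apply_filter(name: str, values: np.ndarray, spacing) -> np.ndarray:
    """Apply one named filter to a 3-D array (spacing in mm per axis)."""
    x = values.astype(np.float64)
    amax = float(np.abs(x).max()) or 1.0
    if name == "original":
        return x
    if name.startswith("wavelet-"):
        return _wavelet_bands(x)[name]
    if name.startswith("log-sigma-"):
        sigma_mm = float(name[len("log-sigma-"):-2])
        sigma_vox = [sigma_mm / s for s in spacing]
        return ndimage.gaussian_laplace(x, sigma=sigma_vox, mode="nearest")
    if name == "square":
        return x**2 / amax
    if name == "squareroot":
        return np.sign(x) * np.sqrt(np.abs(x) * amax)
    if name == "logarithm":
        out = np.sign(x) * np.log(np.abs(x) + 1.0)
        omax = float(np.abs(out).max()) or 1.0
        return out * (amax / omax)
    if name == "exponential":
        c = np.log(amax) / amax
        return np.exp(c * x)
    if name == "gradient":
        grads = [np.gradient(x, s, axis=d) for d, s in enumerate(spacing)]
        return np.sqrt(sum(g * g for g in grads))
    raise ValueError(f"unknown image type {name!r}")


def filter_bank(values: np.ndarray, spacing, image_types: list[str]) -> dict[str, np.ndarray]:
    """Compute all requested filtered images once (wavelet bands shared)."""
    out: dict[str, np.ndarray] = {}
    wavelet_cache: dict[str, np.ndarray] | None = None
    for name in image_types:
        if name.startswith("wavelet-"):
            if wavelet_cache is None:
                wavelet_cache = _wavelet_bands(values.astype(np.float64))
            out[name] = wavelet_cache[name]
        else:
            out[name] = apply_filter(name, values, spacing)
    return out
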
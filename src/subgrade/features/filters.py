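"""Derived (filtered) images from which the intensity/texture battery is re-extracted.

Implemented filters and their naming:

* ``gradient``                — spacing-aware gradient magnitude
* ``exponential``/``logarithm``/``squareroot``/``square``
                              — pointwise maps with range-preserving rescaling
* ``log-sigma-<s>-mm``        — scale-normalised Laplacian of Gaussian at sigma s (mm)
* ``wavelet-<SUB>``           — one-level 3D orthogonal wavelet sub-band (8 bands,
                                SUB in {LLL, LLH, ..., HHH}), coiflet-1 family,
                                reconstructed to the original grid size

The shorthand names ``log`` and ``wavelet`` expand to the default sigma set
{1, 2, 3} mm and all 8 sub-bands respectively.
"""

from __future__ import annotations

import numpy as np
import pywt

from ..image import ImageVolume
from ..subregions import VoxelMask

DEFAULT_LOG_SIGMAS_MM = (1.0, 2.0, 3.0)
DEFAULT_WAVELET = "coif1"
WAVELET_SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
BASE_FILTERS = ("gradient", "exponential", "logarithm", "squareroot", "square")


class FilterConfigError(ValueError):
    """Raised for an unknown filter name."""


def _square(x: np.ndarray) -> np.ndarray:
    amax = np.abs(x).max()
    if amax == 0:
        return np.zeros_like(x)
    c = 1.0 / np.sqrt(amax)
    return (c * x) ** 2


def _squareroot(x: np.ndarray) -> np.ndarray:
    amax = np.abs(x).max()
    if amax == 0:
        return np.zeros_like(x)
    return np.sign(x) * np.sqrt(amax * np.abs(x))


def _logarithm(x: np.ndarray) -> np.ndarray:
    out = np.sign(x) * np.log(np.abs(x) + 1.0)
    amax_in, amax_out = np.abs(x).max(), np.abs(out).max()
    if amax_out == 0:
        return out
    return out * (amax_in / amax_out)


def _exponential(x: np.ndarray) -> np.ndarray:
    amax = np.abs(x).max()
    c = np.log(amax) / amax if amax > 0 else 1.0
    return np.exp(c * x)


def _gradient(x: np.ndarray, spacing: tuple[float, float, float]) -> np.ndarray:
    grads = np.gradient(x, *spacing)
    return np.sqrt(sum(g**2 for g in grads))


def _log_filter(x: np.ndarray, spacing: tuple[float, float, float], sigma_mm: float) -> np.ndarray:
    # scale-normalised Laplacian of Gaussian via the recursive-Gaussian
    # filter (exact zero response on constants, sigma in physical mm)
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(x))
    img.SetSpacing(tuple(reversed([float(s) for s in spacing])))
    f = sitk.LaplacianRecursiveGaussianImageFilter()
    f.SetSigma(float(sigma_mm))
    f.SetNormalizeAcrossScale(True)
    return sitk.GetArrayFromImage(f.Execute(img)).astype(np.float64)


def _wavelet_bands(x: np.ndarray, wavelet: str) -> dict[str, np.ndarray]:
    coeffs = pywt.dwtn(x, wavelet, mode="symmetric")
    bands: dict[str, np.ndarray] = {}
    for key, arr in coeffs.items():
        single = {k: (arr if k == key else None) for k in coeffs}
        rec = pywt.idwtn(single, wavelet, mode="symmetric")
        rec = rec[tuple(slice(0, s) for s in x.shape)]
        sub = key.upper().replace("A", "L").replace("D", "H")
        bands[f"wavelet-{sub}"] = rec
    return bands


def expand_filter_names(
    filters: tuple[str, ...] | list[str],
    log_sigmas_mm: tuple[float, ...] = DEFAULT_LOG_SIGMAS_MM,
) -> list[str]:
    """Expand shorthand names; raise on unknown filters."""
    out: list[str] = []
    for f in filters:
        if f in BASE_FILTERS:
            out.append(f)
        elif f == "log":
            out.extend(_log_name(s) for s in log_sigmas_mm)
        elif f.startswith("log-sigma-"):
            _parse_log_sigma(f)
            out.append(f)
        elif f == "wavelet":
            out.extend(f"wavelet-{sub}" for sub in WAVELET_SUBBANDS)
        elif f.startswith("wavelet-"):
            if f.removeprefix("wavelet-") not in WAVELET_SUBBANDS:
                raise FilterConfigError(f"unknown wavelet sub-band: {f}")
            out.append(f)
        else:
            raise FilterConfigError(f"unknown filter name: {f}")
    return out


def _log_name(sigma_mm: float) -> str:
    s = f"{sigma_mm:g}".replace(".", "-")
    return f"log-sigma-{s}-mm"


def _parse_log_sigma(name: str) -> float:
    body = name.removeprefix("log-sigma-").removesuffix("-mm")
    try:
        return float(body.replace("-", "."))
    except ValueError as err:
        raise FilterConfigError(f"cannot parse LoG sigma from {name!r}") from err


def filter_images(
    image: ImageVolume,
    mask: VoxelMask,
    filters: tuple[str, ...] | list[str],
    wavelet: str = DEFAULT_WAVELET,
    log_sigmas_mm: tuple[float, ...] = DEFAULT_LOG_SIGMAS_MM,
) -> dict[str, ImageVolume]:
    """Compute the requested filter images; each pairs with the original mask."""
    names = expand_filter_names(filters, log_sigmas_mm)
    x = image.grid
    sp = image.spacing_mm
    out: dict[str, ImageVolume] = {}
    wavelet_cache: dict[str, np.ndarray] | None = None
    for name in names:
        if name == "gradient":
            arr = _gradient(x, sp)
        elif name == "exponential":
            arr = _exponential(x)
        elif name == "logarithm":
            arr = _logarithm(x)
        elif name == "squareroot":
            arr = _squareroot(x)
        elif name == "square":
            arr = _square(x)
        elif name.startswith("log-sigma-"):
            arr = _log_filter(x, sp, _parse_log_sigma(name))
        elif name.startswith("wavelet-"):
            if wavelet_cache is None:
                wavelet_cache = _wavelet_bands(x, wavelet)
            arr = wavelet_cache[name]
        else:  # pragma: no cover - expand_filter_names already validated
            raise FilterConfigError(name)
        out[name] = ImageVolume(arr, sp)
    return out
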
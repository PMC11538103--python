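"""Preprocessing: bias correction, denoising, isotropic resampling, standardization.

The pipeline order is bias -> denoise -> resample -> standardize; only
resampling changes the spacing metadata.  Standardization maps a robust
intensity window onto [0, 255] so that the pre-screen thresholds (80, 120)
are portable across acquisitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import Volume

__all__ = ["PreprocessConfig", "correct_bias", "denoise", "resample_isotropic",
           "standardize_intensity", "preprocess"]


@dataclass
class PreprocessConfig:
    target_spacing: float = 0.10          # mm, isotropic working resolution
    denoise_method: str = "mean"          # {mean, median, none}
    denoise_kernel: int = 3               # voxels, odd
    bias_correction: str = "n4"           # {n4, polynomial, none}
    bias_poly_degree: int = 3
    standardize_range: tuple[float, float] = (0.0, 255.0)
    robust_percentiles: tuple[float, float] = (0.5, 99.5)

    def __post_init__(self) -> None:
        if self.target_spacing <= 0:
            raise ValueError("target_spacing must be > 0")
        if self.denoise_kernel < 1 or self.denoise_kernel % 2 == 0:
            raise ValueError("denoise_kernel must be odd and >= 1")
        if self.denoise_method not in ("mean", "median", "none"):
            raise ValueError(f"unknown denoise_method {self.denoise_method!r}")
        if self.bias_correction not in ("n4", "polynomial", "none"):
            raise ValueError(f"unknown bias_correction {self.bias_correction!r}")


# ---------------------------------------------------------------------------
# bias field

def _polynomial_field(data: np.ndarray, degree: int) -> np.ndarray:
    """Smooth multiplicative field: least-squares polynomial fit to log intensities."""
    shape = data.shape
    axes = [np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1) for n in shape]
    u, v, w = np.meshgrid(*axes, indexing="ij")
    terms = []
    for i in range(degree + 1):
        for j in range(degree + 1 - i):
            for k in range(degree + 1 - i - j):
                terms.append((u**i * v**j * w**k).ravel())
    A = np.stack(terms, axis=1)
    y = np.log(data.ravel())
    # subsample for speed on big grids; the field is low-order anyway
    n = len(y)
    if n > 200_000:
        step = n // 200_000 + 1
        coef, *_ = np.linalg.lstsq(A[::step], y[::step], rcond=None)
    else:
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    field = np.exp(A @ coef).reshape(shape)
    return field / field.mean()


def _n4_field(data: np.ndarray, spacing) -> np.ndarray:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(data.T, dtype=np.float64))
    img.SetSpacing(tuple(float(s) for s in spacing))
    shrink = max(1, min(data.shape) // 24)
    small = sitk.Shrink(img, [shrink] * 3) if shrink > 1 else img
    corrector = sitk.N4BiasFieldCorrectionImageFilter()
    corrector.SetMaximumNumberOfIterations([30, 30, 30])
    corrector.Execute(small)
    log_field = corrector.GetLogBiasFieldAsImage(img)
    field = np.exp(sitk.GetArrayFromImage(log_field)).T
    return field / field.mean()


def correct_bias(v: Volume, config: PreprocessConfig | None = None) -> Volume:
    """Divide out an estimated smooth multiplicative intensity field.

    The field is strictly positive and normalized so the corrected volume
    keeps its mean intensity within 1%.  An all-constant volume passes
    through unchanged; non-positive intensities are shifted positive for
    the fit and the shift reversed afterwards.
    """
    config = config or PreprocessConfig()
    data = np.asarray(v.data, dtype=np.float64)
    if config.bias_correction == "none" or np.ptp(data) == 0:
        return v.with_data(data.copy())

    shift = 0.0
    if data.min() <= 0:
        shift = -data.min() + 1e-3 * (np.ptp(data) + 1.0)
        data = data + shift

    if config.bias_correction == "n4":
        try:
            field = _n4_field(data, v.spacing)
        except Exception:  # pragma: no cover - SimpleITK unavailable or failed
            field = _polynomial_field(data, config.bias_poly_degree)
    else:
        field = _polynomial_field(data, config.bias_poly_degree)

    corrected = data / field
    corrected *= data.mean() / corrected.mean()   # preserve mean exactly
    corrected -= shift
    return v.with_data(corrected)


# ---------------------------------------------------------------------------
# denoising

def denoise(v: Volume, config: PreprocessConfig | None = None) -> Volume:
    """Linear mean filter (or median) of the configured kernel; constant regions unchanged."""
    config = config or PreprocessConfig()
    k = config.denoise_kernel
    if config.denoise_method == "none" or k == 1:
        return v.with_data(np.asarray(v.data, dtype=np.float64).copy())
    if config.denoise_method == "mean":
        out = ndimage.uniform_filter(np.asarray(v.data, dtype=np.float64), size=k, mode="nearest")
    else:
        out = ndimage.median_filter(np.asarray(v.data, dtype=np.float64), size=k, mode="nearest")
    return v.with_data(out)


# ---------------------------------------------------------------------------
# resampling

def resample_isotropic(v: Volume, target_spacing: float) -> Volume:
    """Trilinear resampling onto an isotropic grid of `target_spacing` mm.

    The output physical extent matches the input extent to within one
    target voxel.  Masks should be resampled with nearest-neighbor
    (:func:`resample_mask`) so they stay binary.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be > 0")
    if target_spacing < 0.01:
        raise ValueError("target_spacing below 0.01 mm rejected (memory guard)")
    return _resample(v, target_spacing, order=1)


def resample_mask(mask: np.ndarray, spacing, target_spacing: float) -> np.ndarray:
    vol = Volume(np.asarray(mask, dtype=np.float64), spacing)
    out = _resample(vol, target_spacing, order=0)
    return (out.data > 0.5).astype(np.uint8)


def _resample(v: Volume, target: float, order: int) -> Volume:
    shape = v.shape
    spacing = np.asarray(v.spacing)
    extent = (np.asarray(shape) - 1) * spacing
    new_shape = np.floor(extent / target + 1e-9).astype(int) + 1
    coords = np.meshgrid(*[np.arange(n) * target / spacing[a] for a, n in enumerate(new_shape)],
                         indexing="ij")
    out = ndimage.map_coordinates(np.asarray(v.data, dtype=np.float64), coords,
                                  order=order, mode="nearest")
    return Volume(out, spacing=(target,) * 3, origin=v.origin,
                  intensity_scale=v.intensity_scale)


# ---------------------------------------------------------------------------
# standardization

def standardize_intensity(v: Volume, out_range: tuple[float, float] = (0.0, 255.0),
                          percentiles: tuple[float, float] = (0.5, 99.5)) -> Volume:
    """Linear rescale of a robust intensity window onto `out_range`.

    The window is [p0.5, p99.5] by default, guarding against hot voxels;
    values outside it are clipped to the range ends.  Already-standardized
    volumes pass through unchanged (idempotence); a constant volume maps to
    the range midpoint with a warning.
    """
    if v.intensity_scale == "standardized":
        return v.with_data(np.asarray(v.data, dtype=np.float64).copy())
    lo, hi = out_range
    data = np.asarray(v.data, dtype=np.float64)
    rmin, rmax = np.percentile(data, percentiles)
    if rmax <= rmin:
        warnings.warn("constant volume: standardization maps to range midpoint")
        out = np.full_like(data, (lo + hi) / 2.0)
    else:
        out = (data - rmin) / (rmax - rmin) * (hi - lo) + lo
        out = np.clip(out, lo, hi)
    return v.with_data(out, intensity_scale="standardized")


def preprocess(v: Volume, config: PreprocessConfig | None = None) -> Volume:
    """Full chain: bias -> denoise -> resample -> standardize."""
    config = config or PreprocessConfig()
    out = correct_bias(v, config) if v.intensity_scale == "raw" else v
    out = denoise(out, config)
    out = resample_isotropic(out, config.target_spacing)
    if out.intensity_scale == "raw":
        out = standardize_intensity(out, config.standardize_range, config.robust_percentiles)
    return out
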
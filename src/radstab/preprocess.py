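"""Map preprocessing: B-spline resampling, fixed-bin-width discretization,
and image filters.

Quantitative maps carry physically meaningful intensities (ms), so gray-level
discretization uses a *fixed bin width* rather than a fixed bin count:

    level(x) = floor((x - min_ROI) / w) + 1

which preserves the correspondence between gray levels and intensity
differences across subjects.  Resampling interpolates the map with a cubic
B-spline on a grid whose origin coincides with the original grid origin; the
ROI mask is resampled with nearest-neighbour interpolation so it stays
binary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt
import SimpleITK as sitk
from scipy import ndimage

from .image import MIN_ROI_PIXELS, QuantitativeMap, ROIMask, check_geometry

__all__ = [
    "FILTERS",
    "PreprocessConfig",
    "DiscretizedMap",
    "resample",
    "discretize",
    "check_level_range",
    "apply_filter",
]

#: supported filter identifiers, in the canonical report order
FILTERS = (
    "original",
    "gradient",
    "square",
    "squareroot",
    "wavelet_HH",
    "wavelet_HL",
    "wavelet_LH",
    "wavelet_LL",
)


@dataclass(frozen=True)
class PreprocessConfig:
    """One preprocessing combination.

    ``target_spacing`` of ``None`` skips resampling (native grid).
    ``rescale_power_filters`` maps square/square-root outputs linearly back
    to the original intensity range so the fixed bin width keeps comparable
    semantics across filters.  ``wavelet_boundary`` selects the boundary
    mode of the stationary wavelet transform ('wrap' preserves the exact
    sub-band reconstruction identity; 'mirror' is symmetric padding).
    """

    target_spacing: float | None = None  # mm, isotropic in-plane
    bin_width: float = 6.0  # ms
    filter_id: str = "original"
    rescale_power_filters: bool = True
    wavelet_boundary: str = "wrap"

    def __post_init__(self) -> None:
        if self.target_spacing is not None and self.target_spacing <= 0:
            raise ValueError("target_spacing must be positive")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.filter_id not in FILTERS:
            raise ValueError(f"unknown filter_id {self.filter_id!r}; valid: {FILTERS}")


@dataclass(frozen=True)
class DiscretizedMap:
    """Gray-level image defined inside the ROI.

    ``levels`` holds positive integer gray levels at ROI pixels and 0
    elsewhere; ``n_levels`` is the number of quantization levels (the
    maximum level inside the ROI).
    """

    levels: np.ndarray  # int array, 0 outside ROI
    mask: np.ndarray  # bool array
    n_levels: int
    bin_width: float
    spacing: tuple[float, float]

    def roi_levels(self) -> np.ndarray:
        """1D array of levels at ROI pixels."""
        return self.levels[self.mask]


def resample(
    qmap: QuantitativeMap, mask: ROIMask, target_spacing: float
) -> tuple[QuantitativeMap, ROIMask]:
    """Resample map and mask to an isotropic in-plane ``target_spacing``.

    Output size per axis is ``ceil(size * spacing / target)``; the output
    grid origin is aligned with the input origin.  The map uses cubic
    B-spline interpolation, the mask nearest-neighbour.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    check_geometry(qmap, mask)
    if qmap.spacing == (float(target_spacing), float(target_spacing)):
        # grid already at the target spacing: interpolation is the identity
        return qmap, mask

    rows, cols = qmap.shape
    out_rows = math.ceil(rows * qmap.spacing[0] / target_spacing)
    out_cols = math.ceil(cols * qmap.spacing[1] / target_spacing)

    def _resample_one(values: np.ndarray, interpolator) -> np.ndarray:
        img = sitk.GetImageFromArray(np.asarray(values))
        img.SetSpacing((qmap.spacing[1], qmap.spacing[0]))
        img.SetOrigin((qmap.origin[1], qmap.origin[0]))
        res = sitk.Resample(
            img,
            (out_cols, out_rows),
            sitk.Transform(),
            interpolator,
            img.GetOrigin(),
            (float(target_spacing), float(target_spacing)),
            img.GetDirection(),
            0.0,
            img.GetPixelID(),
        )
        return sitk.GetArrayFromImage(res)

    new_values = _resample_one(qmap.values, sitk.sitkBSpline)
    new_mask = _resample_one(mask.values.astype(np.uint8), sitk.sitkNearestNeighbor)

    if new_mask.sum() < MIN_ROI_PIXELS:
        raise ValueError(
            f"resampling to {target_spacing} mm left {int(new_mask.sum())} ROI "
            f"pixels (< {MIN_ROI_PIXELS})"
        )
    spacing = (float(target_spacing), float(target_spacing))
    return (
        QuantitativeMap(values=new_values, spacing=spacing, origin=qmap.origin),
        ROIMask(values=new_mask, spacing=spacing, origin=mask.origin),
    )


def discretize(
    qmap: QuantitativeMap, mask: ROIMask, bin_width: float
) -> DiscretizedMap:
    """Fixed-bin-width gray-level discretization over the ROI."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    check_geometry(qmap, mask)
    roi = qmap.values[mask.values]
    if roi.size == 0:
        raise ValueError("empty ROI")
    if not np.all(np.isfinite(roi)):
        raise ValueError("non-finite values inside ROI")
    lo = roi.min()
    levels = np.zeros(qmap.shape, dtype=np.int64)
    levels[mask.values] = np.floor((roi - lo) / bin_width).astype(np.int64) + 1
    n_levels = int(levels[mask.values].max())
    return DiscretizedMap(
        levels=levels,
        mask=mask.values.copy(),
        n_levels=n_levels,
        bin_width=float(bin_width),
        spacing=qmap.spacing,
    )


def check_level_range(
    cohort: list[tuple[QuantitativeMap, ROIMask]],
    bin_width: float,
    lo: int = 30,
    hi: int = 130,
) -> list[bool]:
    """Per-subject flag: does the quantization level count fall in [lo, hi]?

    Used to validate that a candidate bin width respects the 30-130
    level-count rule for every subject of the cohort.
    """
    if lo > hi:
        raise ValueError("lo must be <= hi")
    flags = []
    for qmap, mask in cohort:
        n = discretize(qmap, mask, bin_width).n_levels
        flags.append(lo <= n <= hi)
    return flags


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def _rescale_to_range(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    lo, hi = reference.min(), reference.max()
    vlo, vhi = values.min(), values.max()
    if vhi == vlo:
        return np.full_like(values, (lo + hi) / 2.0)
    return (values - vlo) / (vhi - vlo) * (hi - lo) + lo


def _swt_subband(
    values: np.ndarray, kind: str, boundary: str = "wrap"
) -> np.ndarray:
    """Single-level stationary (undecimated) Daubechies-3 2D sub-band.

    ``kind`` is two letters, first for the horizontal (column) axis, second
    for the vertical (row) axis; L = low-pass, H = high-pass.  The output
    grid matches the input grid.
    """
    wavelet = pywt.Wavelet("db3")
    taps = {"L": np.asarray(wavelet.dec_lo), "H": np.asarray(wavelet.dec_hi)}
    horiz, vert = kind[0], kind[1]
    # correlate1d applies the (reversed) decomposition filter without
    # decimation; axis 1 is horizontal, axis 0 vertical
    out = ndimage.correlate1d(values, taps[horiz][::-1], axis=1, mode=boundary)
    out = ndimage.correlate1d(out, taps[vert][::-1], axis=0, mode=boundary)
    return out


def swt_reconstruct(subbands: dict[str, np.ndarray]) -> np.ndarray:
    """Invert :func:`_swt_subband` from the four sub-bands (periodic
    boundary).  For an orthonormal wavelet the undecimated analysis/synthesis
    pair satisfies |H|^2 + |G|^2 = 2 per axis, so correlating each sub-band
    with the time-reversed analysis filters and summing recovers 4x the
    input."""
    wavelet = pywt.Wavelet("db3")
    taps = {"L": np.asarray(wavelet.dec_lo), "H": np.asarray(wavelet.dec_hi)}
    acc = np.zeros_like(next(iter(subbands.values())))
    for kind, band in subbands.items():
        horiz, vert = kind[0], kind[1]
        out = ndimage.correlate1d(band, taps[horiz], axis=1, mode="wrap", origin=-1)
        out = ndimage.correlate1d(out, taps[vert], axis=0, mode="wrap", origin=-1)
        acc += out
    return acc / 4.0


def apply_filter(
    qmap: QuantitativeMap,
    mask: ROIMask,
    filter_id: str,
    *,
    rescale_power_filters: bool = True,
    wavelet_boundary: str = "wrap",
) -> QuantitativeMap:
    """Apply one of the supported filters to the whole map grid.

    original     identity
    gradient     spacing-aware magnitude of the 2D spatial gradient
    square       per-pixel square, optionally rescaled to the input range
    squareroot   per-pixel sqrt of absolute value, rescaled likewise
    wavelet_XY   stationary Daubechies-3 sub-band (X horizontal, Y vertical)
    """
    check_geometry(qmap, mask)
    v = qmap.values
    if filter_id == "original":
        return qmap
    if filter_id == "gradient":
        gy, gx = np.gradient(v, qmap.spacing[0], qmap.spacing[1])
        return qmap.with_values(np.hypot(gy, gx))
    if filter_id == "square":
        out = v**2
        if rescale_power_filters:
            out = _rescale_to_range(out, v)
        return qmap.with_values(out)
    if filter_id == "squareroot":
        out = np.sqrt(np.abs(v))
        if rescale_power_filters:
            out = _rescale_to_range(out, v)
        return qmap.with_values(out)
    if filter_id.startswith("wavelet_"):
        kind = filter_id.removeprefix("wavelet_")
        if sorted(kind) not in (["H", "H"], ["H", "L"], ["L", "L"]) or len(kind) != 2:
            raise ValueError(f"unknown filter_id {filter_id!r}")
        return qmap.with_values(_swt_subband(v, kind, boundary=wavelet_boundary))
    raise ValueError(f"unknown filter_id {filter_id!r}; valid: {FILTERS}")
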
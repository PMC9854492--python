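"""Containers for single-slice quantitative maps and their ROI masks.

A :class:`QuantitativeMap` is a 2D scalar image whose values are physical
quantities in milliseconds (e.g. myocardial T1 or T2 relaxation times), with
an in-plane pixel spacing in millimetres.  A :class:`ROIMask` is a binary
image on the identical grid delimiting the region (e.g. the myocardium) over
which features are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

#: minimum number of foreground pixels for a usable ROI
MIN_ROI_PIXELS = 9

# 4-connectivity structuring element
_CROSS = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class QuantitativeMap:
    """Single-slice 2D scalar map.

    Parameters
    ----------
    values
        2D float array, row-major ``(rows, cols)``; units are milliseconds
        for raw relaxation-time maps (filtered maps inherit derived units).
    spacing
        In-plane pixel spacing ``(row_mm, col_mm)``.
    origin
        Physical coordinate of the first pixel centre ``(row_mm, col_mm)``.
    """

    values: np.ndarray
    spacing: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.size == 0:
            raise ValueError("map values must be a non-empty 2D array")
        if not np.all(np.isfinite(values)):
            raise ValueError("map values must be finite")
        spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if spacing[0] <= 0 or spacing[1] <= 0:
            raise ValueError(f"pixel spacing must be positive, got {spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(
            self, "origin", (float(self.origin[0]), float(self.origin[1]))
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area(self) -> float:
        """Physical area of one pixel in mm^2."""
        return self.spacing[0] * self.spacing[1]

    def with_values(self, values: np.ndarray) -> "QuantitativeMap":
        """Same grid geometry, new values (used by filters)."""
        return QuantitativeMap(values=values, spacing=self.spacing, origin=self.origin)


@dataclass(frozen=True)
class ROIMask:
    """Binary region-of-interest mask on the grid of its map.

    The foreground must be a single 4-connected region of at least
    ``MIN_ROI_PIXELS`` pixels.
    """

    values: np.ndarray
    spacing: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        raw = np.asarray(self.values)
        if raw.ndim != 2 or raw.size == 0:
            raise ValueError("mask must be a non-empty 2D array")
        uniq = np.unique(raw)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask must be binary (0/1), found values {uniq}")
        values = raw.astype(bool)
        n = int(values.sum())
        if n < MIN_ROI_PIXELS:
            raise ValueError(
                f"ROI has {n} foreground pixels; at least {MIN_ROI_PIXELS} required"
            )
        _, n_components = ndimage.label(values, structure=_CROSS)
        if n_components != 1:
            raise ValueError(
                f"ROI foreground must be a single 4-connected region, found {n_components}"
            )
        spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if spacing[0] <= 0 or spacing[1] <= 0:
            raise ValueError(f"pixel spacing must be positive, got {spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(
            self, "origin", (float(self.origin[0]), float(self.origin[1]))
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_count(self) -> int:
        return int(self.values.sum())

    @property
    def area_mm2(self) -> float:
        """Physical ROI area: pixel count x pixel area."""
        return self.pixel_count * self.spacing[0] * self.spacing[1]


def check_geometry(qmap: QuantitativeMap, mask: ROIMask) -> None:
    """Raise if map and mask do not share grid geometry."""
    if qmap.shape != mask.shape:
        raise ValueError(f"map shape {qmap.shape} != mask shape {mask.shape}")
    if not np.allclose(qmap.spacing, mask.spacing):
        raise ValueError(f"map spacing {qmap.spacing} != mask spacing {mask.spacing}")
    if not np.allclose(qmap.origin, mask.origin):
        raise ValueError(f"map origin {qmap.origin} != mask origin {mask.origin}")
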
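"""First-order (intensity) features.

The 14 statistical features act on raw ROI intensities, before any
discretization.  Entropy and Uniformity are intensity-histogram features
computed on the fixed-bin-width gray levels.  Kurtosis follows the Pearson
(non-excess) convention — the excess kurtosis plus an offset of 3 — matching
the software convention the reference feature catalogue documents.
"""

from __future__ import annotations

import logging

import numpy as np

from ..image import QuantitativeMap, ROIMask, check_geometry
from ..preprocess import DiscretizedMap

logger = logging.getLogger(__name__)

__all__ = ["first_order_features"]


def first_order_features(
    qmap: QuantitativeMap, mask: ROIMask, disc: DiscretizedMap
) -> dict[str, float]:
    """The 16 first-order features (14 raw-intensity statistics + histogram
    Entropy/Uniformity).  On a constant ROI, Skewness and Kurtosis are
    undefined and returned as NaN."""
    check_geometry(qmap, mask)
    x = qmap.values[mask.values].astype(float)
    n = x.size
    mean = x.mean()
    centered = x - mean
    m2 = np.mean(centered**2)
    m3 = np.mean(centered**3)
    m4 = np.mean(centered**4)

    if m2 > 0:
        skewness = m3 / m2**1.5
        kurtosis = m4 / m2**2  # Pearson convention: excess kurtosis + 3
    else:
        logger.warning("constant ROI: Skewness/Kurtosis undefined, returning NaN")
        skewness = np.nan
        kurtosis = np.nan

    p10, p90 = np.percentile(x, [10, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = np.mean(np.abs(robust - robust.mean())) if robust.size else np.nan

    levels = disc.roi_levels()
    counts = np.bincount(levels)[1:]  # levels are 1-based
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    return {
        "Energy": float((x**2).sum()),
        "Entropy": entropy,
        "Kurtosis": float(kurtosis),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(centered))),
        "Median": float(np.median(x)),
        "Minimum": float(x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Range": float(x.max() - x.min()),
        "RobustMeanAbsoluteDeviation": float(rmad),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": float(skewness),
        "Uniformity": uniformity,
        "Variance": float(m2),
    }
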
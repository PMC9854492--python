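"""Feature extraction orchestration: resample -> filter -> discretize ->
per-class features, producing canonical 98-feature (unfiltered) or
89-feature (filtered) vectors and cohort feature matrices."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..image import QuantitativeMap, ROIMask
from ..preprocess import PreprocessConfig, apply_filter, discretize, resample
from . import manifest
from .firstorder import first_order_features
from .shape2d import shape2d_features
from .texture import (
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = ["TextureConfig", "FeatureVector", "extract_features", "extract_matrix"]


@dataclass(frozen=True)
class TextureConfig:
    """Texture-matrix parameters: Chebyshev pixel distance for neighbour
    definitions and the GLDM coarseness parameter alpha."""

    distance: int = 1
    gldm_alpha: int = 0

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if self.gldm_alpha < 0:
            raise ValueError("gldm_alpha must be >= 0")


@dataclass(frozen=True)
class FeatureVector:
    """Ordered feature names and values for one subject/configuration."""

    names: tuple[str, ...]
    values: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for name in self.names:
            cls = manifest.feature_class(name)
            counts[cls] = counts.get(cls, 0) + 1
        return counts


def extract_features(
    qmap: QuantitativeMap,
    mask: ROIMask,
    preprocess: PreprocessConfig,
    texture: TextureConfig = TextureConfig(),
) -> FeatureVector:
    """Full single-subject pipeline.

    Unfiltered configurations yield 98 features; filtered ones omit the
    shape class (89), since ROI morphology is filter-independent.
    """
    if preprocess.target_spacing is not None:
        qmap, mask = resample(qmap, mask, preprocess.target_spacing)
    filtered = apply_filter(
        qmap,
        mask,
        preprocess.filter_id,
        rescale_power_filters=preprocess.rescale_power_filters,
        wavelet_boundary=preprocess.wavelet_boundary,
    )
    disc = discretize(filtered, mask, preprocess.bin_width)

    by_class: dict[str, dict[str, float]] = {}
    if preprocess.filter_id == "original":
        by_class["shape2d"] = shape2d_features(mask)
    by_class["firstorder"] = first_order_features(filtered, mask, disc)
    by_class["glcm"] = glcm_features(disc, texture.distance)
    by_class["glrlm"] = glrlm_features(disc)
    by_class["glszm"] = glszm_features(disc)
    by_class["gldm"] = gldm_features(disc, texture.gldm_alpha)
    by_class["ngtdm"] = ngtdm_features(disc)

    names = manifest.canonical_names(preprocess.filter_id)
    values = np.empty(len(names))
    for k, name in enumerate(names):
        cls, feat = manifest.split_name(name, preprocess.filter_id)
        values[k] = by_class[cls][feat]
    return FeatureVector(names=tuple(names), values=values)


def extract_matrix(
    cohort: list[tuple[QuantitativeMap, ROIMask]],
    preprocess: PreprocessConfig,
    texture: TextureConfig = TextureConfig(),
    subject_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Subjects x features table for one preprocessing combination."""
    if subject_ids is None:
        subject_ids = [f"subject{k:03d}" for k in range(len(cohort))]
    rows = []
    for sid, (qmap, mask) in zip(subject_ids, cohort):
        try:
            rows.append(extract_features(qmap, mask, preprocess, texture).as_series())
        except ValueError as exc:
            raise ValueError(f"{sid}: {exc}") from exc
    fm = pd.DataFrame(rows, index=subject_ids)
    fm.index.name = "subject"
    return fm
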
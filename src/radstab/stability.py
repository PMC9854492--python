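"""Stability of selected-feature subsets across preprocessing settings.

Each dimensionality reduction yields a binary presence vector over the d
features; stacking the M vectors gives the selection matrix Z.  The
stability estimator of Nogueira, Sechidis & Brown (JMLR 2018) is

    index = 1 - mean_f( s_f^2 ) / ( (kbar/d) * (1 - kbar/d) )

where s_f^2 is the unbiased (M-1 denominator) sample variance of column f
and kbar the mean subset size.  The index equals 1 iff all subsets are
identical, is ~0 for uniformly random subsets of fixed size, and can be
negative (anti-consensus); values >= 0.5 are conventionally read as good
stability.  The raw estimator is reported without clipping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import manifest

__all__ = [
    "GOOD_STABILITY",
    "SelectionMatrix",
    "StabilityReport",
    "stability_index",
    "selection_frequency",
    "frequency_heatmap",
]

#: conventional "good stability" cut-off
GOOD_STABILITY = 0.5


@dataclass(frozen=True)
class SelectionMatrix:
    """Binary M x d matrix: rows are preprocessing combinations, columns
    features; 1 marks a feature retained by that combination."""

    Z: np.ndarray
    feature_names: tuple[str, ...] | None = None
    row_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        Z = np.asarray(self.Z)
        if Z.ndim != 2:
            raise ValueError("Z must be 2D")
        if not np.all(np.isin(Z, (0, 1))):
            raise ValueError("Z entries must be 0/1")
        if Z.shape[0] < 2:
            raise ValueError("at least 2 subsets (rows) required")
        object.__setattr__(self, "Z", Z.astype(float))
        if self.feature_names is not None and len(self.feature_names) != Z.shape[1]:
            raise ValueError("feature_names length mismatch")
        if self.row_labels is not None and len(self.row_labels) != Z.shape[0]:
            raise ValueError("row_labels length mismatch")

    @property
    def M(self) -> int:
        return self.Z.shape[0]

    @property
    def d(self) -> int:
        return self.Z.shape[1]

    @property
    def subset_sizes(self) -> np.ndarray:
        return self.Z.sum(axis=1)

    @property
    def mean_size(self) -> float:
        return float(self.subset_sizes.mean())


@dataclass(frozen=True)
class StabilityReport:
    index: float
    M: int
    d: int
    mean_size: float
    frequency: np.ndarray

    @property
    def good(self) -> bool:
        return self.index >= GOOD_STABILITY


def stability_index(sel: SelectionMatrix) -> StabilityReport:
    """Evaluate the subset-stability estimator on a selection matrix.

    Undefined (raises) when the mean subset size is 0 or d, where the
    normaliser vanishes.
    """
    kbar = sel.mean_size
    d = sel.d
    if kbar <= 0 or kbar >= d:
        raise ValueError(
            f"stability undefined for mean subset size {kbar} with d={d} "
            "(all-empty or all-full selections)"
        )
    col_var = sel.Z.var(axis=0, ddof=1)
    pbar = kbar / d
    index = 1.0 - float(col_var.mean()) / (pbar * (1.0 - pbar))
    return StabilityReport(
        index=index,
        M=sel.M,
        d=d,
        mean_size=kbar,
        frequency=selection_frequency(sel),
    )


def selection_frequency(sel: SelectionMatrix) -> np.ndarray:
    """Per-feature selection ratio: times retained / times selectable."""
    return sel.Z.mean(axis=0)


def frequency_heatmap(
    freq: pd.DataFrame,
    path_prefix,
    class_partition: dict[str, list[str]] | None = None,
) -> tuple:
    """Class-partitioned selection-frequency heatmaps.

    ``freq`` is features x conditions with values in [0, 1].  One panel is
    drawn per feature class, rows = features of the class, columns = swept
    parameter values.  A CSV twin of the full matrix is written alongside.
    """
    from pathlib import Path

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if class_partition is None:
        class_partition = {}
        for name in freq.index:
            class_partition.setdefault(manifest.feature_class(name), []).append(name)
    unknown = set(class_partition) - set(manifest.CLASS_ROSTERS)
    if unknown:
        raise ValueError(f"unknown feature classes: {sorted(unknown)}")
    covered = {f for feats in class_partition.values() for f in feats}
    missing = set(freq.index) - covered
    if missing:
        raise ValueError(f"class partition does not cover: {sorted(missing)[:5]} ...")

    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = prefix.with_name(prefix.name + "_frequency.csv")
    png_path = prefix.with_name(prefix.name + "_frequency.png")
    freq.to_csv(csv_path)

    panels = [c for c in manifest.PANEL_ORDER if c in class_partition]
    heights = [max(len(class_partition[c]), 2) for c in panels]
    fig, axes = plt.subplots(
        len(panels),
        1,
        figsize=(0.6 * freq.shape[1] + 4, 0.28 * sum(heights) + 2 * len(panels)),
        gridspec_kw={"height_ratios": heights},
        squeeze=False,
    )
    for ax, cls in zip(axes[:, 0], panels):
        feats = class_partition[cls]
        block = freq.loc[feats]
        im = ax.imshow(block.to_numpy(), vmin=0, vmax=1, aspect="auto", cmap="viridis_r")
        ax.set_yticks(range(len(feats)))
        ax.set_yticklabels([f.split("_")[-1] for f in feats], fontsize=6)
        ax.set_xticks(range(freq.shape[1]))
        ax.set_xticklabels(freq.columns, fontsize=6, rotation=45)
        ax.set_title(cls, fontsize=8)
        fig.colorbar(im, ax=ax, label="selection ratio")
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return csv_path, png_path
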
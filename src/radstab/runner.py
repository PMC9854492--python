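"""Factorial preprocessing sweeps (Effects A, B, C) over a cohort.

Effect A varies the resampling voxel size at each fixed discretization bin
width; Effect B varies the bin width at each fixed voxel size; Effect C
varies the image filter at a single fixed (voxel size, bin width).  For
every combination the subjects x features matrix is built, the collinearity
analysis and the correlation-based elimination are run for each method
(Pearson / Spearman), and per-sweep selection matrices feed the stability
index and the per-feature selection-frequency heatmaps.

Feature matrices are cached per (voxel size, bin width, filter) so Effects
A and B share their 63-combination grid, and so that switching the
correlation method reuses the extraction work.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortSpec, generate_cohort
from .collinearity import (
    CollinearityConfig,
    count_supra_threshold,
    pairwise_correlation,
)
from .features import TextureConfig, extract_matrix, manifest
from .image import QuantitativeMap, ROIMask
from .preprocess import FILTERS, PreprocessConfig
from .reduction import reduce as reduce_features
from .stability import SelectionMatrix, StabilityReport, frequency_heatmap, stability_index

logger = logging.getLogger(__name__)

__all__ = [
    "VOXEL_SIZES",
    "T1_BIN_WIDTHS",
    "T2_BIN_WIDTHS",
    "EffectSpec",
    "ComboResult",
    "SweepGroup",
    "EffectResult",
    "run_effect",
    "run_all_effects",
    "summarize",
]

#: default resampling voxel sizes (mm)
VOXEL_SIZES = (1.8, 1.9, 2.0, 2.1, 2.2, 2.3, 2.4)
#: default fixed-bin-width sweeps (ms)
T1_BIN_WIDTHS = (3.60, 3.95, 4.30, 4.65, 5.00, 5.35, 5.70, 6.05, 6.40)
T2_BIN_WIDTHS = (0.49, 0.50, 0.51, 0.52, 0.53, 0.54, 0.55, 0.56, 0.57)
#: Effect C fixed parameters
FIXED_VOXEL_SIZE = 2.1
T1_FIXED_BIN_WIDTH = 6.0
T2_FIXED_BIN_WIDTH = 0.56
#: Effect C filter rows, report order
FILTER_ORDER = (
    "original",
    "gradient",
    "square",
    "squareroot",
    "wavelet_HH",
    "wavelet_HL",
    "wavelet_LH",
    "wavelet_LL",
)


def default_bin_widths(map_kind: str) -> tuple[float, ...]:
    return T1_BIN_WIDTHS if map_kind == "T1like" else T2_BIN_WIDTHS


def default_fixed_bin_width(map_kind: str) -> float:
    return T1_FIXED_BIN_WIDTH if map_kind == "T1like" else T2_FIXED_BIN_WIDTH


@dataclass(frozen=True)
class EffectSpec:
    """Declarative description of one sweep."""

    effect: str  # "A" | "B" | "C"
    voxel_sizes: tuple[float, ...] = VOXEL_SIZES
    bin_widths: tuple[float, ...] = T1_BIN_WIDTHS
    filters: tuple[str, ...] = FILTER_ORDER
    fixed_voxel_size: float = FIXED_VOXEL_SIZE
    fixed_bin_width: float = T1_FIXED_BIN_WIDTH

    def __post_init__(self) -> None:
        if self.effect not in ("A", "B", "C"):
            raise ValueError(f"unknown effect {self.effect!r}")
        for f in self.filters:
            if f not in FILTERS:
                raise ValueError(f"unknown filter {f!r}")

    @classmethod
    def for_map_kind(cls, effect: str, map_kind: str) -> "EffectSpec":
        return cls(
            effect=effect,
            bin_widths=default_bin_widths(map_kind),
            fixed_bin_width=default_fixed_bin_width(map_kind),
        )

    def combinations(self) -> list[tuple]:
        """(voxel_size, bin_width, filter) triples of the sweep."""
        if self.effect == "A":
            return [
                (v, w, "original") for w in self.bin_widths for v in self.voxel_sizes
            ]
        if self.effect == "B":
            return [
                (v, w, "original") for v in self.voxel_sizes for w in self.bin_widths
            ]
        return [
            (self.fixed_voxel_size, self.fixed_bin_width, f) for f in self.filters
        ]

    def groups(self) -> list[tuple[str, list[tuple]]]:
        """Sweep groups: (group label, ordered combination keys).

        Effect A groups by fixed bin width (M = #voxel sizes), Effect B by
        fixed voxel size (M = #bin widths), Effect C is one group over the
        filters (M = #filters).
        """
        if self.effect == "A":
            return [
                (f"bw={w:g}", [(v, w, "original") for v in self.voxel_sizes])
                for w in self.bin_widths
            ]
        if self.effect == "B":
            return [
                (f"vs={v:g}", [(v, w, "original") for w in self.bin_widths])
                for v in self.voxel_sizes
            ]
        return [
            (
                "filtering",
                [(self.fixed_voxel_size, self.fixed_bin_width, f) for f in self.filters],
            )
        ]


@dataclass
class ComboResult:
    key: tuple
    n_cc: int
    percent_remaining: float
    remaining: list[str]
    failure: str | None = None


@dataclass
class SweepGroup:
    label: str
    selection: SelectionMatrix
    stability: StabilityReport


@dataclass
class EffectResult:
    spec: EffectSpec
    method: str
    combos: dict[tuple, ComboResult]
    groups: list[SweepGroup]
    feature_names: list[str]


class FeatureCache:
    """Caches subjects x features matrices per preprocessing combination."""

    def __init__(
        self,
        cohort: list[tuple[QuantitativeMap, ROIMask]],
        texture: TextureConfig = TextureConfig(),
    ) -> None:
        self.cohort = cohort
        self.texture = texture
        self._matrices: dict[tuple, pd.DataFrame] = {}

    def matrix(self, voxel_size: float, bin_width: float, filter_id: str) -> pd.DataFrame:
        key = (round(voxel_size, 6), round(bin_width, 6), filter_id)
        if key not in self._matrices:
            t0 = time.perf_counter()
            cfg = PreprocessConfig(
                target_spacing=voxel_size, bin_width=bin_width, filter_id=filter_id
            )
            self._matrices[key] = extract_matrix(self.cohort, cfg, self.texture)
            logger.info(
                "features %s: %d x %d in %.2f s",
                key,
                *self._matrices[key].shape,
                time.perf_counter() - t0,
            )
        return self._matrices[key]


def run_effect(
    cache: FeatureCache,
    spec: EffectSpec,
    method: str = "pearson",
    *,
    gate_significance: bool = True,
) -> EffectResult:
    """Run one effect sweep for one correlation method."""
    config = CollinearityConfig(method=method)
    combos: dict[tuple, ComboResult] = {}
    selections: dict[tuple, np.ndarray] = {}
    feature_names: list[str] | None = None

    for key in spec.combinations():
        v, w, f = key
        try:
            fm = cache.matrix(v, w, f)
            if spec.effect == "C":
                # filter comparison operates on the shared 89 non-shape features
                fm = fm[[c for c in fm.columns if manifest.feature_class(c) != "shape2d"]]
            corr = pairwise_correlation(fm, config)
            red = reduce_features(corr, gate_significance=gate_significance)
            names = list(fm.columns)
            combos[key] = ComboResult(
                key=key,
                n_cc=count_supra_threshold(corr),
                percent_remaining=red.percent_remaining,
                remaining=red.remaining,
            )
            selections[key] = red.selection_vector(names)
            if f == "original":
                feature_names = names
            elif feature_names is None:
                feature_names = names
        except ValueError as exc:
            logger.error("combination %s failed: %s", key, exc)
            combos[key] = ComboResult(
                key=key, n_cc=-1, percent_remaining=np.nan, remaining=[], failure=str(exc)
            )

    groups: list[SweepGroup] = []
    for label, keys in spec.groups():
        ok_keys = [k for k in keys if combos[k].failure is None]
        if len(ok_keys) < 2:
            logger.error("group %s has <2 successful combinations; skipped", label)
            continue
        if spec.effect == "C":
            # filtered and unfiltered vectors live on different rosters;
            # compare on the shared 89 non-shape features
            f0 = ok_keys[0][2]
            common = [
                "_".join(manifest.split_name(n, f0))
                for n in cache.matrix(*ok_keys[0]).columns
                if manifest.feature_class(n) != "shape2d"
            ]
            Z = []
            for k in ok_keys:
                kept = {
                    "_".join(manifest.split_name(n, k[2])) for n in combos[k].remaining
                }
                Z.append([1 if c in kept else 0 for c in common])
            Z = np.asarray(Z)
            sel = SelectionMatrix(
                Z=Z,
                feature_names=tuple("original_" + c for c in common),
                row_labels=tuple(k[2] for k in ok_keys),
            )
        else:
            Z = np.vstack([selections[k] for k in ok_keys])
            sel = SelectionMatrix(
                Z=Z,
                feature_names=tuple(feature_names),
                row_labels=tuple(str(k) for k in ok_keys),
            )
        groups.append(SweepGroup(label=label, selection=sel, stability=stability_index(sel)))

    return EffectResult(
        spec=spec,
        method=method,
        combos=combos,
        groups=groups,
        feature_names=feature_names or [],
    )


def run_all_effects(
    cohort_spec: CohortSpec,
    effects: tuple[str, ...] = ("A", "B", "C"),
    methods: tuple[str, ...] = ("pearson", "spearman"),
    *,
    gate_significance: bool = True,
    texture: TextureConfig = TextureConfig(),
) -> dict[tuple[str, str], EffectResult]:
    """Generate the cohort and run every requested (effect, method) sweep."""
    cohort = generate_cohort(cohort_spec)
    cache = FeatureCache(cohort, texture)
    results = {}
    for effect in effects:
        spec = EffectSpec.for_map_kind(effect, cohort_spec.map_kind)
        for method in methods:
            logger.info("running effect %s / %s", effect, method)
            results[(effect, method)] = run_effect(
                cache, spec, method, gate_significance=gate_significance
            )
    return results


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def _effect_tables(results: dict[tuple[str, str], EffectResult], effect: str):
    """Counts/percentage tables (one row per fixed parameter, one column
    per swept value) and the two-method stability table."""
    per_method = {}
    stability_cols = {}
    for (eff, method), res in results.items():
        if eff != effect:
            continue
        spec = res.spec
        rows_counts, rows_pct = {}, {}
        for label, keys in spec.groups():
            rows_counts[label] = [res.combos[k].n_cc for k in keys]
            rows_pct[label] = [
                int(round(res.combos[k].percent_remaining)) for k in keys
            ]
        if effect == "A":
            columns = [f"{v:g}mm" for v in spec.voxel_sizes]
        elif effect == "B":
            columns = [f"{w:g}ms" for w in spec.bin_widths]
        else:
            columns = list(spec.filters)
        if effect == "C":
            # single group over filters: report one row per filter instead
            key_list = spec.groups()[0][1]
            counts = pd.DataFrame(
                {
                    "n_cc": [res.combos[k].n_cc for k in key_list],
                    "percent_remaining": [
                        int(round(res.combos[k].percent_remaining)) for k in key_list
                    ],
                },
                index=list(spec.filters),
            )
            per_method[method] = counts
        else:
            per_method[method] = {
                "counts": pd.DataFrame.from_dict(
                    rows_counts, orient="index", columns=columns
                ),
                "percent": pd.DataFrame.from_dict(
                    rows_pct, orient="index", columns=columns
                ),
            }
        stability_cols[method] = {
            g.label: round(g.stability.index, 2) for g in res.groups
        }
    stability = pd.DataFrame(stability_cols)
    return per_method, stability


def summarize(
    results: dict[tuple[str, str], EffectResult], out_dir: str | Path
) -> dict:
    """Write CSV tables, selection-frequency heatmaps and a JSON manifest.

    Table layout mirrors the report structure: per effect a counts table
    and an integer-percentage table (rows = fixed parameter, columns =
    swept values), and a stability table with one column per correlation
    method; Effect C collapses to one row per filter plus a single-row
    stability table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    effects = sorted({eff for eff, _ in results})

    for effect in effects:
        per_method, stability = _effect_tables(results, effect)
        for method, tables in per_method.items():
            if effect == "C":
                p = out / f"effect{effect}_{method}_summary.csv"
                tables.to_csv(p)
                written[f"effect{effect}_{method}_summary"] = str(p)
            else:
                for kind, df in tables.items():
                    p = out / f"effect{effect}_{method}_{kind}.csv"
                    df.to_csv(p)
                    written[f"effect{effect}_{method}_{kind}"] = str(p)
        p = out / f"effect{effect}_stability.csv"
        stability.to_csv(p)
        written[f"effect{effect}_stability"] = str(p)

        # per-feature selection-frequency heatmaps (features x groups)
        for method in {m for e, m in results if e == effect}:
            res = results[(effect, method)]
            if not res.groups:
                continue
            freq = pd.DataFrame(
                {
                    g.label: pd.Series(
                        g.stability.frequency, index=list(g.selection.feature_names)
                    )
                    for g in res.groups
                }
            )
            csv_path, png_path = frequency_heatmap(
                freq, out / f"effect{effect}_{method}"
            )
            written[f"effect{effect}_{method}_frequency_csv"] = str(csv_path)
            written[f"effect{effect}_{method}_frequency_png"] = str(png_path)

    manifest_path = out / "run_manifest.json"
    manifest_obj = {
        "effects": {
            f"{eff}:{method}": {
                "spec": asdict(res.spec),
                "method": method,
                "combinations": {
                    str(k): {
                        "n_cc": c.n_cc,
                        "percent_remaining": c.percent_remaining,
                        "n_remaining": len(c.remaining),
                        "failure": c.failure,
                    }
                    for k, c in res.combos.items()
                },
                "stability": {
                    g.label: {
                        "index": g.stability.index,
                        "M": g.stability.M,
                        "d": g.stability.d,
                        "good": bool(g.stability.good),
                    }
                    for g in res.groups
                },
            }
            for (eff, method), res in results.items()
        },
        "outputs": written,
    }
    manifest_path.write_text(json.dumps(manifest_obj, indent=2))
    written["manifest"] = str(manifest_path)
    return written
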
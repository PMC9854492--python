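"""Pairwise feature collinearity across subjects.

Pearson coefficients come from the product-moment formula on the raw
feature columns; Spearman coefficients are Pearson coefficients of mid-rank
transformed columns.  Two-sided p-values use the t approximation with
n - 2 degrees of freedom (an exact permutation scheme is available for
small cohorts).  Columns with zero variance, or containing NaN (flagged
degenerate features), yield undefined entries that are never counted as
significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CollinearityConfig",
    "CorrelationResult",
    "pairwise_correlation",
    "count_supra_threshold",
    "export_heatmap",
]

#: conventional cut-offs: 0.8 for |Pearson|, 0.9 for |Spearman|
DEFAULT_THRESHOLDS = {"pearson": 0.8, "spearman": 0.9}


@dataclass(frozen=True)
class CollinearityConfig:
    method: str = "pearson"  # "pearson" | "spearman"
    threshold: float | None = None  # defaults to the method's cut-off
    alpha: float = 0.05
    p_method: str = "asymptotic"  # "asymptotic" | "permutation"
    n_permutations: int = 2000
    permutation_seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("pearson", "spearman"):
            raise ValueError(f"unknown method {self.method!r}")
        threshold = (
            DEFAULT_THRESHOLDS[self.method] if self.threshold is None else self.threshold
        )
        if not 0 < threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.p_method not in ("asymptotic", "permutation"):
            raise ValueError(f"unknown p_method {self.p_method!r}")
        object.__setattr__(self, "threshold", float(threshold))


@dataclass
class CorrelationResult:
    feature_names: list[str]
    coefficients: np.ndarray  # symmetric, NaN where undefined
    p_values: np.ndarray
    config: CollinearityConfig

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def eligible_pairs(self) -> np.ndarray:
        """Boolean matrix: defined, significant and supra-threshold."""
        with np.errstate(invalid="ignore"):
            e = (
                np.isfinite(self.coefficients)
                & (np.abs(self.coefficients) >= self.config.threshold)
                & (self.p_values < self.config.alpha)
            )
        np.fill_diagonal(e, False)
        return e


def _t_approx_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        rr = np.clip(r, -1.0, 1.0)
        t = rr * np.sqrt((n - 2) / np.maximum(1.0 - rr**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rr), 1.0)] = 0.0
    p[~np.isfinite(r)] = np.nan
    return p


def _corr_matrix(X: np.ndarray) -> np.ndarray:
    """Product-moment correlation with NaN for degenerate columns."""
    n, d = X.shape
    valid = np.all(np.isfinite(X), axis=0) & (X.std(axis=0) > 0)
    C = np.full((d, d), np.nan)
    if valid.sum() >= 1:
        Z = X[:, valid] - X[:, valid].mean(axis=0)
        Z /= np.sqrt((Z**2).sum(axis=0))
        sub = Z.T @ Z
        np.clip(sub, -1.0, 1.0, out=sub)
        idx = np.flatnonzero(valid)
        C[np.ix_(idx, idx)] = sub
    return C


def pairwise_correlation(
    fm: pd.DataFrame, config: CollinearityConfig = CollinearityConfig()
) -> CorrelationResult:
    """Feature-by-feature correlation across subjects (rows of ``fm``)."""
    n, d = fm.shape
    if n < 3:
        raise ValueError(f"at least 3 subjects required, got {n}")
    if d < 2:
        raise ValueError(f"at least 2 features required, got {d}")
    X = fm.to_numpy(dtype=float)
    if config.method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 0, X)  # mid-ranks on ties
    C = _corr_matrix(X)
    if config.p_method == "asymptotic":
        P = _t_approx_pvalues(C, n)
    else:
        P = _permutation_pvalues(X, C, config)
    np.fill_diagonal(P, 0.0)
    diag = np.einsum("ii->i", C)
    diag[np.isfinite(diag)] = 1.0
    return CorrelationResult(
        feature_names=list(fm.columns), coefficients=C, p_values=P, config=config
    )


def _permutation_pvalues(
    X: np.ndarray, C: np.ndarray, config: CollinearityConfig
) -> np.ndarray:
    """Monte-Carlo permutation p-values: each column is permuted
    independently, breaking every pairwise association, and permuted |r|
    is compared with the observed |r|."""
    rng = np.random.default_rng(config.permutation_seed)
    n, d = X.shape
    exceed = np.zeros((d, d))
    for _ in range(config.n_permutations):
        Xp = np.column_stack([X[rng.permutation(n), k] for k in range(d)])
        Cp = _corr_matrix(Xp)
        with np.errstate(invalid="ignore"):
            exceed += np.abs(Cp) >= np.abs(C) - 1e-12
    P = (exceed + 1.0) / (config.n_permutations + 1.0)
    P[~np.isfinite(C)] = np.nan
    return P


def count_supra_threshold(result: CorrelationResult) -> int:
    """Number of unordered feature pairs that are significant (p < alpha)
    with |coefficient| >= threshold — the "# of CC" report quantity."""
    e = result.eligible_pairs()
    return int(np.triu(e, k=1).sum())


def export_heatmap(result: CorrelationResult, path_prefix) -> tuple:
    """Write the |coefficient| matrix as a PNG heatmap plus coefficient and
    p-value CSVs (undefined cells empty).  Returns the written paths."""
    from pathlib import Path

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    names = result.feature_names

    coeff_csv = prefix.with_name(prefix.name + "_coefficients.csv")
    pval_csv = prefix.with_name(prefix.name + "_pvalues.csv")
    png = prefix.with_name(prefix.name + "_heatmap.png")
    pd.DataFrame(result.coefficients, index=names, columns=names).to_csv(coeff_csv)
    pd.DataFrame(result.p_values, index=names, columns=names).to_csv(pval_csv)

    fig, ax = plt.subplots(figsize=(8, 7))
    masked = np.ma.masked_invalid(np.abs(result.coefficients))
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("lightgray")
    im = ax.imshow(masked, vmin=0, vmax=1, cmap=cmap)
    ax.set_title(f"|{result.config.method} correlation|")
    ax.set_xlabel("feature index")
    ax.set_ylabel("feature index")
    fig.colorbar(im, ax=ax, label="|coefficient|")
    fig.tight_layout()
    fig.savefig(png, dpi=120)
    plt.close(fig)
    return coeff_csv, pval_csv, png
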
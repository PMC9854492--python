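"""Iterative correlation-based feature elimination.

At each step the eligible pair with the largest absolute correlation is
selected; for each member the mean absolute correlation with all other
retained features is computed, and the member with the larger mean is
removed.  The loop repeats until no eligible pair remains.  Correlations
are never recomputed from data — only the retained submatrix shrinks.

Eligibility defaults to "significant AND supra-threshold" (a config switch
restricts the gate to the threshold alone).  All ties break on the
canonical feature order: the earlier-ordered pair wins selection, and the
later-ordered member of the pair is removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .collinearity import CorrelationResult

__all__ = ["RemovalStep", "ReductionResult", "reduce"]


@dataclass(frozen=True)
class RemovalStep:
    removed: str
    pair: tuple[str, str]
    pair_correlation: float
    mean_abs_correlation: float


@dataclass
class ReductionResult:
    remaining: list[str]
    removed: list[RemovalStep]
    threshold: float

    @property
    def percent_remaining(self) -> float:
        """Exact percentage of input features retained."""
        d = len(self.remaining) + len(self.removed)
        return 100.0 * len(self.remaining) / d

    @property
    def percent_remaining_rounded(self) -> int:
        """Report-table convention: integer percentage."""
        return int(round(self.percent_remaining))

    def selection_vector(self, feature_names: list[str]) -> np.ndarray:
        """Binary presence vector over ``feature_names``."""
        kept = set(self.remaining)
        return np.array([1 if f in kept else 0 for f in feature_names], dtype=int)


def _mean_abs_corr(C: np.ndarray, idx: int, active: np.ndarray) -> float:
    """Mean |corr| of feature ``idx`` against the other active features,
    skipping undefined entries."""
    row = C[idx, active]
    row = row[np.isfinite(row)]
    return float(np.abs(row).mean()) if row.size else 0.0


def reduce(
    result: CorrelationResult, *, gate_significance: bool = True
) -> ReductionResult:
    """Run the elimination loop on a precomputed correlation structure."""
    d = result.n_features
    if d == 0:
        raise ValueError("empty correlation result")
    names = result.feature_names
    C = result.coefficients
    eligible = result.eligible_pairs()
    if not gate_significance:
        with np.errstate(invalid="ignore"):
            eligible = np.isfinite(C) & (np.abs(C) >= result.config.threshold)
        np.fill_diagonal(eligible, False)

    active = np.ones(d, dtype=bool)
    trace: list[RemovalStep] = []

    for _ in range(d - 1):  # terminates in <= d-1 removals
        sub = eligible & active[:, None] & active[None, :]
        iu = np.triu(sub, k=1)
        if not iu.any():
            break
        cand_i, cand_j = np.nonzero(iu)
        absc = np.abs(C[cand_i, cand_j])
        best = absc.max()
        # earliest pair in canonical order among exact-max ties
        ties = np.flatnonzero(absc == best)
        order = np.lexsort((cand_j[ties], cand_i[ties]))
        i, j = int(cand_i[ties[order[0]]]), int(cand_j[ties[order[0]]])

        others_i = active.copy()
        others_i[i] = False
        others_j = active.copy()
        others_j[j] = False
        mean_i = _mean_abs_corr(C, i, others_i)
        mean_j = _mean_abs_corr(C, j, others_j)
        # remove the larger mean; tie -> the later-ordered member (j > i)
        drop, mean_drop = (i, mean_i) if mean_i > mean_j else (j, mean_j)

        active[drop] = False
        trace.append(
            RemovalStep(
                removed=names[drop],
                pair=(names[i], names[j]),
                pair_correlation=float(C[i, j]),
                mean_abs_correlation=mean_drop,
            )
        )

    remaining = [names[k] for k in np.flatnonzero(active)]
    return ReductionResult(
        remaining=remaining, removed=trace, threshold=result.config.threshold
    )
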
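import numpy as np
import pytest

from radstab import CohortSpec, QuantitativeMap, ROIMask, generate_subject
from radstab.collinearity import CollinearityConfig, CorrelationResult
from radstab.preprocess import DiscretizedMap


@pytest.fixture(scope="session")
def t1_subject():
    """One deterministic T1-like synthetic subject."""
    spec = CohortSpec(n_subjects=2, seed=11)
    return generate_subject(spec, 0)


@pytest.fixture
def square_roi():
    """64x64 map with a centred 20x20 square ROI at 1 mm spacing."""
    rng = np.random.default_rng(5)
    values = rng.normal(500.0, 30.0, size=(64, 64))
    mask = np.zeros((64, 64), dtype=bool)
    mask[22:42, 22:42] = True
    return (
        QuantitativeMap(values=values, spacing=(1.0, 1.0)),
        ROIMask(values=mask, spacing=(1.0, 1.0)),
    )


def make_disc(levels: np.ndarray, mask: np.ndarray | None = None) -> DiscretizedMap:
    """Build a DiscretizedMap directly from a level grid (tests only)."""
    levels = np.asarray(levels, dtype=np.int64)
    if mask is None:
        mask = levels > 0
    levels = np.where(mask, levels, 0)
    return DiscretizedMap(
        levels=levels,
        mask=np.asarray(mask, dtype=bool),
        n_levels=int(levels.max()),
        bin_width=1.0,
        spacing=(1.0, 1.0),
    )


def corr_result_from_matrix(
    C: np.ndarray,
    names: list[str] | None = None,
    method: str = "pearson",
    threshold: float = 0.8,
    p_values: np.ndarray | None = None,
) -> CorrelationResult:
    """Wrap a coefficient matrix as a CorrelationResult (all significant
    unless explicit p-values are given); tests the reduction loop without
    touching data."""
    C = np.asarray(C, dtype=float)
    d = C.shape[0]
    if names is None:
        names = [f"f{k}" for k in range(d)]
    if p_values is None:
        p_values = np.zeros_like(C)
    return CorrelationResult(
        feature_names=list(names),
        coefficients=C,
        p_values=p_values,
        config=CollinearityConfig(method=method, threshold=threshold),
    )
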
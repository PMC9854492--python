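"""Pairwise Pearson/Spearman correlation, significance gating and
supra-threshold counting."""

import numpy as np
import pandas as pd
import pytest

from radstab import (
    CollinearityConfig,
    count_supra_threshold,
    pairwise_correlation,
)
from radstab.collinearity import export_heatmap

from conftest import corr_result_from_matrix


def _fm(columns: dict) -> pd.DataFrame:
    return pd.DataFrame(columns)


def test_exact_linear_relation_gives_unit_coefficients():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    fm = _fm({"x": x, "y": 2 * x + 1})
    for method in ("pearson", "spearman"):
        res = pairwise_correlation(fm, CollinearityConfig(method=method))
        assert res.coefficients[0, 1] == pytest.approx(1.0)
        assert res.p_values[0, 1] < 1e-6


def test_monotone_nonlinear_relation_separates_methods():
    x = np.linspace(0, 5, 10)
    fm = _fm({"x": x, "y": np.exp(x)})
    pcc = pairwise_correlation(fm, CollinearityConfig(method="pearson"))
    scc = pairwise_correlation(fm, CollinearityConfig(method="spearman"))
    assert scc.coefficients[0, 1] == pytest.approx(1.0)
    assert pcc.coefficients[0, 1] < 1.0


def test_pearson_matches_product_moment_formula():
    a = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
    b = np.array([2.0, 7.0, 1.0, 8.0, 2.0, 8.0])
    res = pairwise_correlation(_fm({"a": a, "b": b}), CollinearityConfig())
    manual = ((a - a.mean()) * (b - b.mean())).sum() / np.sqrt(
        ((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()
    )
    assert res.coefficients[0, 1] == pytest.approx(manual, abs=1e-12)


def test_spearman_invariant_to_monotone_transform():
    rng = np.random.default_rng(4)
    x = rng.normal(size=12)
    y = rng.normal(size=12)
    base = pairwise_correlation(
        _fm({"x": x, "y": y}), CollinearityConfig(method="spearman")
    )
    warped = pairwise_correlation(
        _fm({"x": np.exp(x), "y": y}), CollinearityConfig(method="spearman")
    )
    assert warped.coefficients[0, 1] == pytest.approx(base.coefficients[0, 1])


def test_pvalues_match_scipy():
    from scipy import stats

    rng = np.random.default_rng(8)
    x, y = rng.normal(size=15), rng.normal(size=15)
    res = pairwise_correlation(_fm({"x": x, "y": y}), CollinearityConfig())
    r_ref, p_ref = stats.pearsonr(x, y)
    assert res.coefficients[0, 1] == pytest.approx(r_ref, abs=1e-12)
    assert res.p_values[0, 1] == pytest.approx(p_ref, rel=1e-6)


def test_zero_variance_column_flagged_never_significant():
    fm = _fm({"flat": np.ones(6), "x": np.arange(6.0), "y": np.arange(6.0) * 2})
    res = pairwise_correlation(fm, CollinearityConfig())
    assert np.isnan(res.coefficients[0, 1])
    assert count_supra_threshold(res) == 1  # only the (x, y) pair


def test_fewer_than_three_subjects_rejected():
    fm = _fm({"a": [1.0, 2.0], "b": [2.0, 1.0]})
    with pytest.raises(ValueError, match="3 subjects"):
        pairwise_correlation(fm, CollinearityConfig())


def test_count_known_coefficients_threshold():
    C = np.array([[1.0, 0.95, 0.5], [0.95, 1.0, 0.1], [0.5, 0.1, 1.0]])
    res = corr_result_from_matrix(C, threshold=0.8)
    assert count_supra_threshold(res) == 1


def test_count_identical_features_all_pairs():
    rng = np.random.default_rng(0)
    base = rng.normal(size=10)
    fm = _fm({f"f{k}": base + 1e-9 * rng.normal(size=10) for k in range(5)})
    res = pairwise_correlation(fm, CollinearityConfig())
    assert count_supra_threshold(res) == 5 * 4 // 2


def test_null_count_bounded_by_alpha_expectation():
    rng = np.random.default_rng(123)
    n, d = 200, 12
    fm = pd.DataFrame(
        rng.normal(size=(n, d)), columns=[f"f{k}" for k in range(d)]
    )
    res = pairwise_correlation(fm, CollinearityConfig())
    # with n=200 a |r| >= 0.8 under independence is essentially impossible
    assert count_supra_threshold(res) == 0


def test_count_non_increasing_in_threshold():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(10, 6))
    X[:, 3] = X[:, 0] + 0.1 * rng.normal(size=10)
    fm = pd.DataFrame(X, columns=list("abcdef"))
    counts = [
        count_supra_threshold(
            pairwise_correlation(fm, CollinearityConfig(threshold=t))
        )
        for t in (0.3, 0.5, 0.7, 0.9)
    ]
    assert counts == sorted(counts, reverse=True)


def test_symmetry_and_bounds():
    rng = np.random.default_rng(9)
    fm = pd.DataFrame(rng.normal(size=(8, 5)), columns=list("abcde"))
    for method in ("pearson", "spearman"):
        res = pairwise_correlation(fm, CollinearityConfig(method=method))
        C = res.coefficients
        np.testing.assert_allclose(C, C.T)
        assert np.all(np.abs(C[np.isfinite(C)]) <= 1.0 + 1e-12)
        np.testing.assert_allclose(np.diag(C), 1.0)


def test_permutation_pvalues_agree_with_asymptotic():
    rng = np.random.default_rng(11)
    x = rng.normal(size=20)
    fm = _fm({"x": x, "y": 0.9 * x + 0.4 * rng.normal(size=20), "z": rng.normal(size=20)})
    asym = pairwise_correlation(fm, CollinearityConfig())
    perm = pairwise_correlation(
        fm,
        CollinearityConfig(p_method="permutation", n_permutations=500, permutation_seed=1),
    )
    # strongly correlated pair significant under both schemes
    assert asym.p_values[0, 1] < 0.01 and perm.p_values[0, 1] < 0.01
    # independent pair non-significant under both
    assert asym.p_values[0, 2] > 0.05 and perm.p_values[0, 2] > 0.05


def test_export_heatmap_roundtrip(tmp_path):
    rng = np.random.default_rng(2)
    fm = pd.DataFrame(rng.normal(size=(8, 4)), columns=list("abcd"))
    fm["flat"] = 1.0
    res = pairwise_correlation(fm, CollinearityConfig())
    coeff_csv, pval_csv, png = export_heatmap(res, tmp_path / "corr")
    back = pd.read_csv(coeff_csv, index_col=0)
    np.testing.assert_allclose(
        back.to_numpy(), res.coefficients, atol=1e-9, equal_nan=True
    )
    assert back.shape == (5, 5)
    # undefined cells are empty in the CSV
    assert back["flat"].isna().drop("flat").all()
    assert png.exists()
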
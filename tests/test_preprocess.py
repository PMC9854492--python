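"""Resampling, fixed-bin-width discretization and filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radstab import (
    CohortSpec,
    QuantitativeMap,
    ROIMask,
    apply_filter,
    check_level_range,
    discretize,
    generate_cohort,
    resample,
)
from radstab.preprocess import _swt_subband, swt_reconstruct


def _map_with_square_roi(values, spacing=(2.0, 2.0)):
    values = np.asarray(values, dtype=float)
    mask = np.zeros(values.shape, dtype=bool)
    r, c = values.shape
    mask[r // 4 : 3 * r // 4, c // 4 : 3 * c // 4] = True
    return (
        QuantitativeMap(values=values, spacing=spacing),
        ROIMask(values=mask, spacing=spacing),
    )


# ---------------------------------------------------------------------------
# resample
# ---------------------------------------------------------------------------


def test_resample_output_size_follows_ceil_rule():
    qmap, mask = _map_with_square_roi(np.full((100, 100), 500.0), spacing=(2.0, 2.0))
    out_map, out_mask = resample(qmap, mask, 2.1)
    assert out_map.shape == (96, 96)  # ceil(100 * 2.0 / 2.1)
    assert out_map.spacing == (2.1, 2.1)
    assert out_mask.shape == (96, 96)


def test_resample_constant_map_stays_constant_in_interior():
    qmap, mask = _map_with_square_roi(np.full((100, 100), 500.0))
    out_map, _ = resample(qmap, mask, 2.1)
    interior = out_map.values[:-2, :-2]  # last pixels fall outside the input grid
    np.testing.assert_allclose(interior, 500.0, atol=1e-9)


def test_resample_to_own_spacing_is_identity():
    rng = np.random.default_rng(0)
    qmap, mask = _map_with_square_roi(rng.normal(500, 40, (60, 60)))
    out_map, out_mask = resample(qmap, mask, 2.0)
    np.testing.assert_allclose(out_map.values, qmap.values, atol=1e-9)
    np.testing.assert_array_equal(out_mask.values, mask.values)


def test_resample_mask_stays_binary_and_origin_aligned():
    qmap, mask = _map_with_square_roi(np.full((50, 50), 900.0))
    out_map, out_mask = resample(qmap, mask, 1.8)
    assert set(np.unique(out_mask.values.astype(int))) <= {0, 1}
    assert out_map.origin == qmap.origin


def test_resample_round_trip_on_smooth_map():
    y, x = np.mgrid[0:80, 0:80]
    smooth = 500 + 50 * np.sin(2 * np.pi * x / 60) * np.cos(2 * np.pi * y / 70)
    qmap, mask = _map_with_square_roi(smooth)
    down, dmask = resample(qmap, mask, 2.4)
    back, _ = resample(down, dmask, 2.0)
    n = min(back.shape[0], qmap.shape[0]) - 3
    diff = back.values[:n, :n] - qmap.values[:n, :n]
    rms = np.sqrt(np.mean(diff**2)) / np.sqrt(np.mean(qmap.values[:n, :n] ** 2))
    assert rms < 0.005


def test_resample_empty_roi_fails():
    values = np.full((40, 40), 100.0)
    mask = np.zeros((40, 40), dtype=bool)
    mask[20:23, 20:23] = True  # 9 pixels, vanishes at coarse target
    qmap = QuantitativeMap(values=values, spacing=(1.0, 1.0))
    roi = ROIMask(values=mask, spacing=(1.0, 1.0))
    with pytest.raises(ValueError, match="ROI"):
        resample(qmap, roi, 8.0)


# ---------------------------------------------------------------------------
# discretize
# ---------------------------------------------------------------------------


def test_discretize_floor_rule_hand_case():
    values = np.zeros((2, 2))
    values.flat = [10.0, 12.0, 14.0, 19.0]
    values = np.pad(values, 2, constant_values=5.0)
    mask = np.zeros_like(values, dtype=bool)
    mask[2:4, 2:4] = True
    # pad mask to satisfy the 9-pixel minimum while keeping the hand values
    mask[1, 2:4] = True
    mask[4, 2:4] = True
    mask[2:4, 1] = True
    values[1, 2:4] = values[4, 2:4] = 10.0
    values[2:4, 1] = 10.0
    qmap = QuantitativeMap(values=values, spacing=(1.0, 1.0))
    roi = ROIMask(values=mask, spacing=(1.0, 1.0))
    disc = discretize(qmap, roi, 5.0)
    assert disc.levels[2, 2] == 1  # 10 ms -> level 1
    assert disc.levels[2, 3] == 1  # 12 ms
    assert disc.levels[3, 2] == 1  # 14 ms
    assert disc.levels[3, 3] == 2  # 19 ms
    assert disc.n_levels == 2


def test_discretize_constant_roi_single_level():
    qmap, mask = _map_with_square_roi(np.full((20, 20), 321.0))
    disc = discretize(qmap, mask, 6.0)
    assert disc.n_levels == 1
    assert np.all(disc.roi_levels() == 1)


def test_discretize_range_774_bw6_gives_130_levels():
    values = np.full((20, 20), 100.0)
    values[8, 8] = 100.0 + 774.0
    qmap, mask = _map_with_square_roi(values)
    disc = discretize(qmap, mask, 6.0)
    assert disc.n_levels == 130  # floor(774/6) + 1


@given(
    st.lists(st.floats(0, 1000), min_size=2, max_size=30),
    st.floats(0.5, 20),
)
@settings(max_examples=60, deadline=None)
def test_discretize_monotone_in_values(roi_values, w):
    x = np.sort(np.asarray(roi_values))
    lev = np.floor((x - x.min()) / w).astype(int) + 1
    assert np.all(np.diff(lev) >= 0)


def test_n_levels_weakly_decreasing_in_bin_width(t1_subject):
    qmap, mask = t1_subject
    widths = np.linspace(2.0, 12.0, 15)
    ns = [discretize(qmap, mask, w).n_levels for w in widths]
    assert all(a >= b for a, b in zip(ns, ns[1:]))


def test_check_level_range_flags_subjects():
    cohort = generate_cohort(CohortSpec(n_subjects=4, seed=13))
    # huge bin width -> single level everywhere -> all out of [30, 130]
    assert check_level_range(cohort, 1e6) == [False] * 4
    flags = check_level_range(cohort, 6.0)
    direct = [30 <= discretize(m, k, 6.0).n_levels <= 130 for m, k in cohort]
    assert flags == direct


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def test_gradient_of_plane_is_constant_slope():
    y, x = np.mgrid[0:40, 0:40].astype(float)
    qmap, mask = _map_with_square_roi(3.0 + 2.5 * x, spacing=(2.0, 2.0))
    out = apply_filter(qmap, mask, "gradient")
    interior = out.values[1:-1, 1:-1]
    np.testing.assert_allclose(interior, 2.5 / 2.0, atol=1e-9)  # per-mm slope


def test_square_filter_of_constant_map_is_constant():
    qmap, mask = _map_with_square_roi(np.full((30, 30), 7.0))
    out = apply_filter(qmap, mask, "square")
    np.testing.assert_allclose(out.values, 7.0)


def test_square_and_squareroot_preserve_intensity_range():
    rng = np.random.default_rng(3)
    qmap, mask = _map_with_square_roi(rng.uniform(100, 900, (40, 40)))
    for fid in ("square", "squareroot"):
        out = apply_filter(qmap, mask, fid)
        assert np.isclose(out.values.min(), qmap.values.min())
        assert np.isclose(out.values.max(), qmap.values.max())


def test_wavelet_hh_annihilates_constant():
    qmap, mask = _map_with_square_roi(np.full((32, 32), 555.0))
    out = apply_filter(qmap, mask, "wavelet_HH")
    assert np.abs(out.values[4:-4, 4:-4]).max() < 1e-9


def test_wavelet_subbands_reconstruct_input():
    rng = np.random.default_rng(8)
    x = rng.standard_normal((48, 40))
    bands = {k: _swt_subband(x, k) for k in ("LL", "LH", "HL", "HH")}
    rec = swt_reconstruct(bands)
    assert np.abs(rec - x).max() < 1e-8


def test_unknown_filter_rejected(t1_subject):
    qmap, mask = t1_subject
    with pytest.raises(ValueError, match="filter"):
        apply_filter(qmap, mask, "laplacian")
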
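"""Texture matrix builders against brute-force enumerators.

The oracles below enumerate pixel pairs, runs, zones, dependences and
neighbourhoods with plain Python loops, independently of the vectorised
builders they check.
"""

import numpy as np
import pytest

from radstab.features.matrices import (
    DIRECTIONS,
    glcm_matrix,
    gldm_matrix,
    glrlm_matrix,
    glszm_matrix,
    ngtdm_matrix,
)

from conftest import make_disc

N_TRIALS = 120


def random_disc(rng, max_side=8, max_levels=5):
    """Random level grid with a random (possibly partial) mask."""
    rows = rng.integers(2, max_side + 1)
    cols = rng.integers(2, max_side + 1)
    levels = rng.integers(1, max_levels + 1, size=(rows, cols))
    mask = rng.random((rows, cols)) < 0.8
    if not mask.any():
        mask[0, 0] = True
    levels = np.where(mask, levels, 0)
    # renumber so n_levels = max level present
    return make_disc(levels, mask)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def brute_glcm(disc, offset):
    ng = disc.n_levels
    P = np.zeros((ng, ng))
    rows, cols = disc.levels.shape
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + offset[0], c + offset[1]
            if 0 <= r2 < rows and 0 <= c2 < cols:
                if disc.mask[r, c] and disc.mask[r2, c2]:
                    P[disc.levels[r, c] - 1, disc.levels[r2, c2] - 1] += 1
    P = P + P.T  # symmetric
    return P / P.sum() if P.sum() else None


def brute_glrlm(disc, offset):
    """Enumerate maximal runs by walking every pixel along the direction."""
    rows, cols = disc.levels.shape
    runs = {}
    dr, dc = offset
    for r in range(rows):
        for c in range(cols):
            if not disc.mask[r, c]:
                continue
            pr, pc = r - dr, c - dc
            starts_run = not (
                0 <= pr < rows
                and 0 <= pc < cols
                and disc.mask[pr, pc]
                and disc.levels[pr, pc] == disc.levels[r, c]
            )
            if not starts_run:
                continue
            length = 0
            rr, cc = r, c
            while (
                0 <= rr < rows
                and 0 <= cc < cols
                and disc.mask[rr, cc]
                and disc.levels[rr, cc] == disc.levels[r, c]
            ):
                length += 1
                rr += dr
                cc += dc
            runs[(disc.levels[r, c], length)] = runs.get(
                (disc.levels[r, c], length), 0
            ) + 1
    max_run = max((l for (_, l) in runs), default=1)
    P = np.zeros((disc.n_levels, max_run))
    for (g, l), count in runs.items():
        P[g - 1, l - 1] = count
    return P


def brute_glszm(disc):
    rows, cols = disc.levels.shape
    seen = np.zeros((rows, cols), dtype=bool)
    zones = []
    for r in range(rows):
        for c in range(cols):
            if disc.mask[r, c] and not seen[r, c]:
                g = disc.levels[r, c]
                stack, size = [(r, c)], 0
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    size += 1
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            nr, nc = rr + dr, cc + dc
                            if (
                                0 <= nr < rows
                                and 0 <= nc < cols
                                and disc.mask[nr, nc]
                                and not seen[nr, nc]
                                and disc.levels[nr, nc] == g
                            ):
                                seen[nr, nc] = True
                                stack.append((nr, nc))
                zones.append((g, size))
    max_size = max(s for _, s in zones)
    P = np.zeros((disc.n_levels, max_size))
    for g, s in zones:
        P[g - 1, s - 1] += 1
    return P


def brute_gldm(disc, alpha=0):
    rows, cols = disc.levels.shape
    entries = []
    for r in range(rows):
        for c in range(cols):
            if not disc.mask[r, c]:
                continue
            dep = 1  # centre included
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if (dr, dc) == (0, 0):
                        continue
                    nr, nc = r + dr, c + dc
                    if (
                        0 <= nr < rows
                        and 0 <= nc < cols
                        and disc.mask[nr, nc]
                        and abs(int(disc.levels[nr, nc]) - int(disc.levels[r, c]))
                        <= alpha
                    ):
                        dep += 1
            entries.append((disc.levels[r, c], dep))
    max_dep = max(d for _, d in entries)
    P = np.zeros((disc.n_levels, max_dep))
    for g, d in entries:
        P[g - 1, d - 1] += 1
    return P


def brute_ngtdm(disc):
    rows, cols = disc.levels.shape
    s = np.zeros(disc.n_levels)
    n = np.zeros(disc.n_levels)
    for r in range(rows):
        for c in range(cols):
            if not disc.mask[r, c]:
                continue
            neigh = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if (dr, dc) == (0, 0):
                        continue
                    nr, nc = r + dr, c + dc
                    if 0 <= nr < rows and 0 <= nc < cols and disc.mask[nr, nc]:
                        neigh.append(disc.levels[nr, nc])
            if neigh:
                g = disc.levels[r, c]
                s[g - 1] += abs(g - np.mean(neigh))
                n[g - 1] += 1
    return s, n


# ---------------------------------------------------------------------------
# randomized equivalence
# ---------------------------------------------------------------------------


def test_matrix_builders_match_brute_force_on_random_grids():
    rng = np.random.default_rng(99)
    for _ in range(N_TRIALS):
        disc = random_disc(rng)
        for angle, offset in DIRECTIONS.items():
            P = glcm_matrix(disc, angle)
            B = brute_glcm(disc, offset)
            if B is None:
                assert P is None
            else:
                np.testing.assert_allclose(P, B, atol=1e-12)
            np.testing.assert_allclose(
                glrlm_matrix(disc, angle), brute_glrlm(disc, offset), atol=1e-12
            )
        np.testing.assert_allclose(glszm_matrix(disc), brute_glszm(disc), atol=1e-12)
        np.testing.assert_allclose(gldm_matrix(disc), brute_gldm(disc), atol=1e-12)
        s, n = ngtdm_matrix(disc)
        bs, bn = brute_ngtdm(disc)
        np.testing.assert_allclose(s, bs, atol=1e-9)
        np.testing.assert_allclose(n, bn, atol=1e-12)


# ---------------------------------------------------------------------------
# hand cases
# ---------------------------------------------------------------------------


def test_glcm_checkerboard_hand_case():
    disc = make_disc([[1, 2], [2, 1]])
    P = glcm_matrix(disc, 0)
    np.testing.assert_allclose(P, [[0.0, 0.5], [0.5, 0.0]])


def test_glcm_constant_roi_is_one_by_one():
    disc = make_disc(np.ones((3, 3), dtype=int))
    P = glcm_matrix(disc, 0)
    np.testing.assert_allclose(P, [[1.0]])


def test_glcm_normalization_sums_to_one():
    rng = np.random.default_rng(1)
    disc = random_disc(rng)
    for angle in DIRECTIONS:
        P = glcm_matrix(disc, angle)
        if P is not None:
            assert P.sum() == pytest.approx(1.0)


def test_glrlm_single_run_per_row():
    disc = make_disc(np.full((5, 5), 2, dtype=int))
    P = glrlm_matrix(disc, 0)  # 5 horizontal runs of length 5, level 2
    assert P.shape == (2, 5)
    assert P[1, 4] == 5
    assert P.sum() == 5


def test_gldm_constant_grid_interior_dependence():
    disc = make_disc(np.ones((4, 4), dtype=int))
    P = gldm_matrix(disc, alpha=0)
    # 4 corners dep=4, 8 edges dep=6, 4 interior dep=9 (centre included)
    assert P[0, 3] == 4 and P[0, 5] == 8 and P[0, 8] == 4
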
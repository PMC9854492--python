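"""Gray-level texture matrix builders (GLCM, GLRLM, GLSZM, GLDM, NGTDM).

All builders act on a :class:`~radstab.preprocess.DiscretizedMap`: an
integer gray-level image defined inside the ROI.  Pixel neighbourhoods use
the Chebyshev norm at distance 1 (the 8-neighbourhood); directional matrices
(GLCM, GLRLM) are built per 2D angle — 0, 45, 90, 135 degrees — and the
corresponding features are averaged over directions by the caller.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..preprocess import DiscretizedMap

__all__ = [
    "DIRECTIONS",
    "glcm_matrix",
    "glrlm_matrix",
    "glszm_matrix",
    "gldm_matrix",
    "ngtdm_matrix",
]

#: angle (degrees) -> pixel offset (drow, dcol)
DIRECTIONS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}

#: the 8-neighbourhood (Chebyshev distance 1)
_NEIGHBOUR_OFFSETS = [
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
]


def _shifted_pairs(disc: DiscretizedMap, offset: tuple[int, int]):
    """Levels of all pixel pairs (a, b) with b = a + offset, both in ROI."""
    dr, dc = offset
    rows, cols = disc.levels.shape
    r0, r1 = max(0, -dr), min(rows, rows - dr)
    c0, c1 = max(0, -dc), min(cols, cols - dc)
    if r0 >= r1 or c0 >= c1:
        return None
    src = np.s_[r0:r1, c0:c1]
    dst = np.s_[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = disc.mask[src] & disc.mask[dst]
    if not valid.any():
        return None
    return disc.levels[src][valid], disc.levels[dst][valid]


def glcm_matrix(
    disc: DiscretizedMap,
    angle: int,
    distance: int = 1,
    *,
    symmetric: bool = True,
    normalize: bool = True,
) -> np.ndarray | None:
    """Gray-level co-occurrence matrix for one direction.

    Counts pairs of ROI pixels separated by ``distance`` times the angle
    offset; with ``symmetric`` both offset signs are accumulated, and with
    ``normalize`` the matrix is scaled to sum 1.  Returns ``None`` when the
    direction has no valid pixel pair.
    """
    dr, dc = DIRECTIONS[angle]
    pairs = _shifted_pairs(disc, (dr * distance, dc * distance))
    if pairs is None:
        return None
    a, b = pairs
    ng = disc.n_levels
    P = np.zeros((ng, ng), dtype=float)
    np.add.at(P, (a - 1, b - 1), 1.0)
    if symmetric:
        P = P + P.T
    if normalize:
        P /= P.sum()
    return P


def _iter_lines(shape: tuple[int, int], angle: int):
    """Index arrays of all maximal lattice lines along one direction."""
    rows, cols = shape
    if angle == 0:
        for r in range(rows):
            yield np.full(cols, r), np.arange(cols)
    elif angle == 90:
        for c in range(cols):
            yield np.arange(rows), np.full(rows, c)
    elif angle == 135:  # main diagonals (dr=+1, dc=+1 traversal)
        for off in range(-(rows - 1), cols):
            r = np.arange(max(0, -off), min(rows, cols - off))
            yield r, r + off
    elif angle == 45:  # anti-diagonals (dr=-1, dc=+1 traversal)
        for s in range(rows + cols - 1):
            r = np.arange(min(s, rows - 1), max(0, s - cols + 1) - 1, -1)
            yield r, s - r
    else:  # pragma: no cover
        raise ValueError(f"unsupported angle {angle}")


def glrlm_matrix(disc: DiscretizedMap, angle: int) -> np.ndarray:
    """Gray-level run length matrix for one direction.

    Entry ``(i, l)`` counts maximal runs of ``l+1`` consecutive ROI pixels
    of level ``i+1`` along the direction; runs are broken by out-of-ROI
    pixels.
    """
    ng = disc.n_levels
    rows, cols = disc.levels.shape
    max_run = max(rows, cols)
    P = np.zeros((ng, max_run), dtype=float)
    for r_idx, c_idx in _iter_lines((rows, cols), angle):
        line = disc.levels[r_idx, c_idx]
        inroi = disc.mask[r_idx, c_idx]
        n = line.size
        if n == 0:
            continue
        # run boundaries: change of level, or change of ROI membership
        boundaries = np.flatnonzero(
            (line[1:] != line[:-1]) | (inroi[1:] != inroi[:-1])
        )
        starts = np.concatenate([[0], boundaries + 1])
        ends = np.concatenate([boundaries + 1, [n]])
        for s, e in zip(starts, ends):
            if inroi[s]:
                P[line[s] - 1, e - s - 1] += 1.0
    # trim trailing all-zero run-length columns
    used = np.flatnonzero(P.sum(axis=0))
    return P[:, : used.max() + 1] if used.size else P[:, :1]


def glszm_matrix(disc: DiscretizedMap) -> np.ndarray:
    """Gray-level size zone matrix: entry ``(i, s)`` counts 8-connected
    zones of ``s+1`` ROI pixels with level ``i+1``."""
    ng = disc.n_levels
    structure = np.ones((3, 3), dtype=bool)  # 8-connectivity
    # restrict to the ROI bounding box for speed
    rr, cc = np.nonzero(disc.mask)
    box = np.s_[rr.min() : rr.max() + 1, cc.min() : cc.max() + 1]
    levels = disc.levels[box]
    mask = disc.mask[box]
    zone_sizes: dict[int, list[int]] = {}
    max_size = 1
    for g in np.unique(levels[mask]):
        lab, n_zones = ndimage.label((levels == g) & mask, structure=structure)
        if n_zones == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        zone_sizes[int(g)] = sizes.tolist()
        max_size = max(max_size, int(sizes.max()))
    P = np.zeros((ng, max_size), dtype=float)
    for g, sizes in zone_sizes.items():
        for s in sizes:
            P[g - 1, s - 1] += 1.0
    return P


def gldm_matrix(disc: DiscretizedMap, alpha: int = 0) -> np.ndarray:
    """Gray-level dependence matrix.

    For each ROI pixel, the dependence count is 1 (the centre pixel) plus
    the number of 8-neighbours inside the ROI whose level differs by at
    most ``alpha``.  Entry ``(i, j)`` counts ROI pixels of level ``i+1``
    with dependence ``j+1``.
    """
    ng = disc.n_levels
    levels = disc.levels
    mask = disc.mask
    dep = np.zeros(levels.shape, dtype=np.int64)
    rows, cols = levels.shape
    for dr, dc in _NEIGHBOUR_OFFSETS:
        r0, r1 = max(0, -dr), min(rows, rows - dr)
        c0, c1 = max(0, -dc), min(cols, cols - dc)
        src = np.s_[r0:r1, c0:c1]
        dst = np.s_[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ok = (
            mask[src]
            & mask[dst]
            & (np.abs(levels[src] - levels[dst]) <= alpha)
        )
        dep[src] += ok
    dep_roi = dep[mask] + 1  # centre pixel included
    lev_roi = levels[mask]
    P = np.zeros((ng, int(dep_roi.max())), dtype=float)
    np.add.at(P, (lev_roi - 1, dep_roi - 1), 1.0)
    return P


def ngtdm_matrix(disc: DiscretizedMap) -> tuple[np.ndarray, np.ndarray]:
    """Neighbourhood gray-tone difference matrix.

    Returns ``(s, n)`` indexed by gray level (1-based at index 0): ``s[i]``
    is the summed absolute difference between level ``i+1`` and the mean of
    each pixel's valid (in-ROI) neighbours; ``n[i]`` is the pixel count.
    Pixels without any in-ROI neighbour are excluded.
    """
    ng = disc.n_levels
    levels = disc.levels
    mask = disc.mask
    rows, cols = levels.shape
    nb_sum = np.zeros(levels.shape, dtype=float)
    nb_cnt = np.zeros(levels.shape, dtype=np.int64)
    for dr, dc in _NEIGHBOUR_OFFSETS:
        r0, r1 = max(0, -dr), min(rows, rows - dr)
        c0, c1 = max(0, -dc), min(cols, cols - dc)
        src = np.s_[r0:r1, c0:c1]
        dst = np.s_[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ok = mask[dst]
        nb_sum[src] += np.where(ok, levels[dst], 0)
        nb_cnt[src] += ok
    valid = mask & (nb_cnt > 0)
    diff = np.abs(levels[valid] - nb_sum[valid] / nb_cnt[valid])
    s = np.zeros(ng, dtype=float)
    n = np.zeros(ng, dtype=float)
    np.add.at(s, levels[valid] - 1, diff)
    np.add.at(n, levels[valid] - 1, 1.0)
    return s, n
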
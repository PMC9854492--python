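"""Texture feature formulas on the gray-level matrices.

GLCM and GLRLM features are evaluated on each 2D directional matrix (0, 45,
90, 135 degrees) and averaged over directions; GLSZM, GLDM and NGTDM are
direction-free.  Features whose denominators vanish on degenerate ROIs
(e.g. GLCM Correlation on a single-level region) are returned as NaN.
"""

from __future__ import annotations

import warnings

import numpy as np

from ..preprocess import DiscretizedMap
from .matrices import (
    DIRECTIONS,
    glcm_matrix,
    gldm_matrix,
    glrlm_matrix,
    glszm_matrix,
    ngtdm_matrix,
)

__all__ = [
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
]


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _average_over_directions(per_direction: list[dict[str, float]]) -> dict[str, float]:
    keys = per_direction[0].keys()
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN directions
        for k in keys:
            out[k] = float(np.nanmean([d[k] for d in per_direction]))
    return out


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


def _glcm_single(P: np.ndarray) -> dict[str, float]:
    ng = P.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)  # == py for symmetric P
    ux = float((i * px).sum())
    sigx2 = float(((i - ux) ** 2 * px).sum())

    # difference distribution p_{|i-j|}(k), k = 0..ng-1
    k_diff = np.arange(ng)
    pd = np.zeros(ng)
    np.add.at(pd, np.abs(ii - jj).ravel(), P.ravel())
    # sum distribution p_{i+j}(k), k = 2..2ng
    k_sum = np.arange(2, 2 * ng + 1)
    ps = np.zeros(2 * ng - 1)
    np.add.at(ps, (ii + jj - 2).ravel(), P.ravel())

    diff_avg = float((k_diff * pd).sum())

    hxy = _entropy(P.ravel())
    hx = _entropy(px)
    # joint independence surrogates for the information measures
    pxpy = np.outer(px, px)
    nz = (P > 0) & (pxpy > 0)
    hxy1 = float(-(P[nz] * np.log2(pxpy[nz])).sum())
    nz2 = pxpy > 0
    hxy2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())

    if hx > 0:
        imc1 = (hxy - hxy1) / hx
    else:
        imc1 = np.nan
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if ng > 1 else np.nan

    corr_num = float((ii * jj * P).sum()) - ux * ux
    correlation = corr_num / sigx2 if sigx2 > 0 else np.nan

    inv_var = float((pd[1:] / k_diff[1:] ** 2).sum()) if ng > 1 else np.nan

    return {
        "Autocorrelation": float((ii * jj * P).sum()),
        "ClusterProminence": float(((ii + jj - 2 * ux) ** 4 * P).sum()),
        "ClusterShade": float(((ii + jj - 2 * ux) ** 3 * P).sum()),
        "ClusterTendency": float(((ii + jj - 2 * ux) ** 2 * P).sum()),
        "Contrast": float(((ii - jj) ** 2 * P).sum()),
        "Correlation": float(correlation),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": _entropy(pd),
        "DifferenceVariance": float(((k_diff - diff_avg) ** 2 * pd).sum()),
        "Id": float((pd / (1.0 + k_diff)).sum()),
        "Idm": float((pd / (1.0 + k_diff**2)).sum()),
        "Idmn": float((pd / (1.0 + (k_diff / ng) ** 2)).sum()),
        "Idn": float((pd / (1.0 + k_diff / ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": float(imc2),
        "InverseVariance": float(inv_var),
        "JointAverage": ux,
        "JointEnergy": float((P**2).sum()),
        "JointEntropy": hxy,
        "MaximumProbability": float(P.max()),
        "SumEntropy": _entropy(ps),
        "SumSquares": sigx2,
    }


def glcm_features(disc: DiscretizedMap, distance: int = 1) -> dict[str, float]:
    per_dir = []
    for angle in DIRECTIONS:
        P = glcm_matrix(disc, angle, distance)
        if P is not None:
            per_dir.append(_glcm_single(P))
    if not per_dir:
        raise ValueError("no direction has a valid pixel pair")
    return _average_over_directions(per_dir)


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------


def _glrlm_single(P: np.ndarray) -> dict[str, float]:
    ng, nr = P.shape
    i = np.arange(1, ng + 1)
    j = np.arange(1, nr + 1)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    nz = P.sum()
    np_pixels = float((P * jj).sum())
    pg = P.sum(axis=1)
    pr = P.sum(axis=0)
    p = P / nz
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())
    return {
        "GrayLevelNonUniformity": float((pg**2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum() / nz**2),
        "GrayLevelVariance": float(((ii - mu_i) ** 2 * p).sum()),
        "HighGrayLevelRunEmphasis": float((pg * i**2).sum() / nz),
        "LongRunEmphasis": float((pr * j**2).sum() / nz),
        "LongRunHighGrayLevelEmphasis": float((P * ii**2 * jj**2).sum() / nz),
        "LongRunLowGrayLevelEmphasis": float((P * jj**2 / ii**2).sum() / nz),
        "LowGrayLevelRunEmphasis": float((pg / i**2).sum() / nz),
        "RunEntropy": _entropy(p.ravel()),
        "RunLengthNonUniformity": float((pr**2).sum() / nz),
        "RunLengthNonUniformityNormalized": float((pr**2).sum() / nz**2),
        "RunPercentage": float(nz / np_pixels),
        "RunVariance": float(((jj - mu_j) ** 2 * p).sum()),
        "ShortRunEmphasis": float((pr / j**2).sum() / nz),
        "ShortRunHighGrayLevelEmphasis": float((P * ii**2 / jj**2).sum() / nz),
        "ShortRunLowGrayLevelEmphasis": float((P / (ii**2 * jj**2)).sum() / nz),
    }


def glrlm_features(disc: DiscretizedMap) -> dict[str, float]:
    per_dir = [_glrlm_single(glrlm_matrix(disc, angle)) for angle in DIRECTIONS]
    return _average_over_directions(per_dir)


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------


def glszm_features(disc: DiscretizedMap) -> dict[str, float]:
    P = glszm_matrix(disc)
    ng, ns = P.shape
    i = np.arange(1, ng + 1)
    s = np.arange(1, ns + 1)
    ii, ss = np.meshgrid(i, s, indexing="ij")
    nz = P.sum()
    np_pixels = float((P * ss).sum())
    pg = P.sum(axis=1)
    pz = P.sum(axis=0)
    p = P / nz
    mu_i = float((ii * p).sum())
    mu_s = float((ss * p).sum())
    return {
        "GrayLevelNonUniformity": float((pg**2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum() / nz**2),
        "GrayLevelVariance": float(((ii - mu_i) ** 2 * p).sum()),
        "HighGrayLevelZoneEmphasis": float((pg * i**2).sum() / nz),
        "LargeAreaEmphasis": float((pz * s**2).sum() / nz),
        "LargeAreaHighGrayLevelEmphasis": float((P * ii**2 * ss**2).sum() / nz),
        "LargeAreaLowGrayLevelEmphasis": float((P * ss**2 / ii**2).sum() / nz),
        "LowGrayLevelZoneEmphasis": float((pg / i**2).sum() / nz),
        "SizeZoneNonUniformity": float((pz**2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((pz**2).sum() / nz**2),
        "SmallAreaEmphasis": float((pz / s**2).sum() / nz),
        "SmallAreaHighGrayLevelEmphasis": float((P * ii**2 / ss**2).sum() / nz),
        "SmallAreaLowGrayLevelEmphasis": float((P / (ii**2 * ss**2)).sum() / nz),
        "ZoneEntropy": _entropy(p.ravel()),
        "ZonePercentage": float(nz / np_pixels),
        "ZoneVariance": float(((ss - mu_s) ** 2 * p).sum()),
    }


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------


def gldm_features(disc: DiscretizedMap, alpha: int = 0) -> dict[str, float]:
    P = gldm_matrix(disc, alpha)
    ng, nd = P.shape
    i = np.arange(1, ng + 1)
    j = np.arange(1, nd + 1)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    nz = P.sum()
    pg = P.sum(axis=1)
    pd = P.sum(axis=0)
    p = P / nz
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())
    return {
        "DependenceEntropy": _entropy(p.ravel()),
        "DependenceNonUniformity": float((pd**2).sum() / nz),
        "DependenceNonUniformityNormalized": float((pd**2).sum() / nz**2),
        "DependenceVariance": float(((jj - mu_j) ** 2 * p).sum()),
        "GrayLevelNonUniformity": float((pg**2).sum() / nz),
        "GrayLevelVariance": float(((ii - mu_i) ** 2 * p).sum()),
        "HighGrayLevelEmphasis": float((pg * i**2).sum() / nz),
        "LargeDependenceEmphasis": float((pd * j**2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((P * ii**2 * jj**2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((P * jj**2 / ii**2).sum() / nz),
        "LowGrayLevelEmphasis": float((pg / i**2).sum() / nz),
        "SmallDependenceEmphasis": float((pd / j**2).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((P * ii**2 / jj**2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((P / (ii**2 * jj**2)).sum() / nz),
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------


def ngtdm_features(disc: DiscretizedMap) -> dict[str, float]:
    s, n = ngtdm_matrix(disc)
    N = n.sum()
    p = n / N
    i = np.arange(1, s.size + 1, dtype=float)
    present = p > 0
    ngp = int(present.sum())
    ip = i[present]
    pp = p[present]
    sp = s[present]

    psum = float((p * s).sum())
    coarseness = 1.0 / psum if psum > 0 else 1e6

    if ngp > 1:
        di = ip[:, None] - ip[None, :]
        pi_pj = pp[:, None] * pp[None, :]
        contrast = (
            float((pi_pj * di**2).sum()) / (ngp * (ngp - 1)) * float(s.sum()) / N
        )
        busy_den = float(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum())
        busyness = psum / busy_den if busy_den > 0 else 0.0
        num = np.abs(di) * (
            (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
            / (pp[:, None] + pp[None, :])
        )
        complexity = float(num.sum()) / N
        s_total = float(s.sum())
        strength = (
            float(((pp[:, None] + pp[None, :]) * di**2).sum()) / s_total
            if s_total > 0
            else 0.0
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
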
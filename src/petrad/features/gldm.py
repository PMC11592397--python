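"""Gray-level dependence matrix features (14 features).

A 26-neighbor is *dependent* on the center voxel when the absolute level
difference is at most ``alpha`` (default 0, i.e. equal levels).  The
dependence size of a voxel counts itself plus its dependent neighbors, so
sizes start at 1.
"""

from __future__ import annotations

import numpy as np

from ._util import ANGLES_13, crop_to_mask, shifted_views, xlogx2

__all__ = ["gldm_features", "gldm_matrix", "GLDM_NAMES"]

GLDM_NAMES = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)


def gldm_matrix(
    levels: np.ndarray, mask: np.ndarray, n_levels: int, alpha: float = 0.0
) -> np.ndarray:
    """Dependence matrix ``P[i-1, d-1]`` with center-inclusive dependence size."""
    dep = np.zeros(mask.shape, dtype=np.int64)
    for angle in ANGLES_13:
        for offset in (angle, tuple(-a for a in angle)):
            lev_a, lev_b = shifted_views(levels, offset)
            m_a, m_b = shifted_views(mask, offset)
            ok = m_a & m_b & (np.abs(lev_a - lev_b) <= alpha)
            base_slice, _ = shifted_views(dep, offset)
            base_slice[ok] += 1
    dep = dep + 1  # include the center voxel
    max_dep = int(dep[mask].max())
    P = np.zeros((n_levels, max_dep), dtype=float)
    np.add.at(P, (levels[mask] - 1, dep[mask] - 1), 1.0)
    return P


def _features_from_matrix(P: np.ndarray) -> dict[str, float]:
    nz = P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=float)
    d = np.arange(1, P.shape[1] + 1, dtype=float)
    pg = P.sum(axis=1)
    pd = P.sum(axis=0)
    p = P / nz
    mu_i = float(np.sum(i * pg / nz))
    mu_d = float(np.sum(d * pd / nz))
    ii = i[:, None]
    dd = d[None, :]
    return {
        "SmallDependenceEmphasis": float(np.sum(pd / d**2) / nz),
        "LargeDependenceEmphasis": float(np.sum(pd * d**2) / nz),
        "GrayLevelNonUniformity": float(np.sum(pg**2) / nz),
        "DependenceNonUniformity": float(np.sum(pd**2) / nz),
        "DependenceNonUniformityNormalized": float(np.sum(pd**2) / nz**2),
        "GrayLevelVariance": float(np.sum(p * (ii - mu_i) ** 2)),
        "DependenceVariance": float(np.sum(p * (dd - mu_d) ** 2)),
        "DependenceEntropy": float(-np.sum(xlogx2(p))),
        "LowGrayLevelEmphasis": float(np.sum(pg / i**2) / nz),
        "HighGrayLevelEmphasis": float(np.sum(pg * i**2) / nz),
        "SmallDependenceLowGrayLevelEmphasis": float(np.sum(P / (ii**2 * dd**2)) / nz),
        "SmallDependenceHighGrayLevelEmphasis": float(np.sum(P * ii**2 / dd**2) / nz),
        "LargeDependenceLowGrayLevelEmphasis": float(np.sum(P * dd**2 / ii**2) / nz),
        "LargeDependenceHighGrayLevelEmphasis": float(np.sum(P * dd**2 * ii**2) / nz),
    }


def gldm_features(levels: np.ndarray, mask: np.ndarray, alpha: float = 0.0) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("GLDM requires a nonempty mask")
    levels, mask = crop_to_mask(np.asarray(levels), mask)
    n_levels = int(levels[mask].max())
    P = gldm_matrix(levels, mask, n_levels, alpha=alpha)
    return _features_from_matrix(P)
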
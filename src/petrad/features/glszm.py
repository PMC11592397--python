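"""Gray-level size-zone matrix features (16 features; zones by 26-connectivity)."""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from ._util import STRUCT26, crop_to_mask, xlogx2

__all__ = ["glszm_features", "glszm_matrix", "GLSZM_NAMES"]

GLSZM_NAMES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)


def glszm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone matrix ``P[i-1, s-1]``: zones are 26-connected components of equal level."""
    max_size = int(mask.sum())
    P = np.zeros((n_levels, max_size), dtype=float)
    for g in np.unique(levels[mask]):
        comp, n = ndi.label((levels == g) & mask, structure=STRUCT26)
        if n == 0:
            continue
        sizes = np.bincount(comp.ravel())[1:]
        for s in sizes:
            P[g - 1, s - 1] += 1
    used = np.nonzero(P.sum(axis=0))[0]
    n_cols = int(used[-1]) + 1 if used.size else 1
    return P[:, :n_cols]


def _features_from_matrix(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    nz = P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=float)
    s = np.arange(1, P.shape[1] + 1, dtype=float)
    pg = P.sum(axis=1)
    ps = P.sum(axis=0)
    p = P / nz
    mu_i = float(np.sum(i * pg / nz))
    mu_s = float(np.sum(s * ps / nz))
    ii = i[:, None]
    ss = s[None, :]
    return {
        "SmallAreaEmphasis": float(np.sum(ps / s**2) / nz),
        "LargeAreaEmphasis": float(np.sum(ps * s**2) / nz),
        "GrayLevelNonUniformity": float(np.sum(pg**2) / nz),
        "GrayLevelNonUniformityNormalized": float(np.sum(pg**2) / nz**2),
        "SizeZoneNonUniformity": float(np.sum(ps**2) / nz),
        "SizeZoneNonUniformityNormalized": float(np.sum(ps**2) / nz**2),
        "ZonePercentage": float(nz / n_voxels),
        "GrayLevelVariance": float(np.sum(p * (ii - mu_i) ** 2)),
        "ZoneVariance": float(np.sum(p * (ss - mu_s) ** 2)),
        "ZoneEntropy": float(-np.sum(xlogx2(p))),
        "LowGrayLevelZoneEmphasis": float(np.sum(pg / i**2) / nz),
        "HighGrayLevelZoneEmphasis": float(np.sum(pg * i**2) / nz),
        "SmallAreaLowGrayLevelEmphasis": float(np.sum(P / (ii**2 * ss**2)) / nz),
        "SmallAreaHighGrayLevelEmphasis": float(np.sum(P * ii**2 / ss**2) / nz),
        "LargeAreaLowGrayLevelEmphasis": float(np.sum(P * ss**2 / ii**2) / nz),
        "LargeAreaHighGrayLevelEmphasis": float(np.sum(P * ii**2 * ss**2) / nz),
    }


def glszm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("GLSZM requires a nonempty mask")
    levels, mask = crop_to_mask(np.asarray(levels), mask)
    n_levels = int(levels[mask].max())
    P = glszm_matrix(levels, mask, n_levels)
    return _features_from_matrix(P, int(mask.sum()))
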
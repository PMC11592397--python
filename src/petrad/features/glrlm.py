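"""Gray-level run-length matrix features (16 features, 13-direction average)."""

from __future__ import annotations

import numpy as np

from ._util import ANGLES_13, crop_to_mask, xlogx2

__all__ = ["glrlm_features", "glrlm_matrix", "GLRLM_NAMES"]

GLRLM_NAMES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)


def glrlm_matrix(
    levels: np.ndarray, mask: np.ndarray, direction: tuple[int, int, int], n_levels: int
) -> np.ndarray:
    """Run-length matrix ``P[i-1, l-1]`` for one direction.

    A run is a maximal set of collinear in-mask voxels of equal gray level.
    """
    shape = mask.shape
    max_len = int(np.ceil(np.sqrt(sum((d * n) ** 2 for d, n in zip(direction, shape))))) + 1
    P = np.zeros((n_levels, max_len), dtype=float)

    def in_bounds(v):
        return all(0 <= v[a] < shape[a] for a in range(3))

    voxels = np.argwhere(mask)
    for v in voxels:
        v = tuple(int(c) for c in v)
        g = levels[v]
        prev = (v[0] - direction[0], v[1] - direction[1], v[2] - direction[2])
        if in_bounds(prev) and mask[prev] and levels[prev] == g:
            continue  # not a run start
        length = 1
        nxt = (v[0] + direction[0], v[1] + direction[1], v[2] + direction[2])
        while in_bounds(nxt) and mask[nxt] and levels[nxt] == g:
            length += 1
            nxt = (nxt[0] + direction[0], nxt[1] + direction[1], nxt[2] + direction[2])
        P[g - 1, length - 1] += 1
    used = np.nonzero(P.sum(axis=0))[0]
    n_cols = int(used[-1]) + 1 if used.size else 1
    return P[:, :n_cols]


def _features_from_matrix(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=float)
    l = np.arange(1, P.shape[1] + 1, dtype=float)
    pg = P.sum(axis=1)  # per gray level
    pl = P.sum(axis=0)  # per run length
    p = P / nr
    mu_i = float(np.sum(i * pg / nr))
    mu_l = float(np.sum(l * pl / nr))
    ii = i[:, None]
    ll = l[None, :]
    return {
        "ShortRunEmphasis": float(np.sum(pl / l**2) / nr),
        "LongRunEmphasis": float(np.sum(pl * l**2) / nr),
        "GrayLevelNonUniformity": float(np.sum(pg**2) / nr),
        "GrayLevelNonUniformityNormalized": float(np.sum(pg**2) / nr**2),
        "RunLengthNonUniformity": float(np.sum(pl**2) / nr),
        "RunLengthNonUniformityNormalized": float(np.sum(pl**2) / nr**2),
        "RunPercentage": float(nr / n_voxels),
        "GrayLevelVariance": float(np.sum(p * (ii - mu_i) ** 2)),
        "RunVariance": float(np.sum(p * (ll - mu_l) ** 2)),
        "RunEntropy": float(-np.sum(xlogx2(p))),
        "LowGrayLevelRunEmphasis": float(np.sum(pg / i**2) / nr),
        "HighGrayLevelRunEmphasis": float(np.sum(pg * i**2) / nr),
        "ShortRunLowGrayLevelEmphasis": float(np.sum(P / (ii**2 * ll**2)) / nr),
        "ShortRunHighGrayLevelEmphasis": float(np.sum(P * ii**2 / ll**2) / nr),
        "LongRunLowGrayLevelEmphasis": float(np.sum(P * ll**2 / ii**2) / nr),
        "LongRunHighGrayLevelEmphasis": float(np.sum(P * ii**2 * ll**2) / nr),
    }


def glrlm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("GLRLM requires a nonempty mask")
    levels, mask = crop_to_mask(np.asarray(levels), mask)
    n_levels = int(levels[mask].max())
    n_voxels = int(mask.sum())
    per_direction = [
        _features_from_matrix(glrlm_matrix(levels, mask, d, n_levels), n_voxels)
        for d in ANGLES_13
    ]
    return {
        name: float(np.mean([d[name] for d in per_direction])) for name in GLRLM_NAMES
    }
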
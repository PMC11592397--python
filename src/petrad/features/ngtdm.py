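"""Neighboring gray-tone difference matrix features (5 features, 26-neighborhood)."""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from ._util import crop_to_mask

__all__ = ["ngtdm_features", "ngtdm_table", "NGTDM_NAMES"]

NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

_COARSENESS_CAP = 1e6  # divergence cap for zero total difference (constant regions)


def ngtdm_table(levels: np.ndarray, mask: np.ndarray, n_levels: int):
    """Per-gray-level counts ``n_i`` and summed absolute differences ``s_i``.

    For each in-mask voxel with at least one in-mask 26-neighbor, the
    difference between its level and the mean level of those neighbors is
    accumulated into ``s`` at its own level.
    """
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    m = mask.astype(float)
    neigh_sum = ndi.convolve(levels * m, kernel, mode="constant", cval=0.0)
    neigh_cnt = ndi.convolve(m, kernel, mode="constant", cval=0.0)
    valid = mask & (neigh_cnt > 0)
    diffs = np.zeros_like(neigh_sum)
    diffs[valid] = np.abs(levels[valid] - neigh_sum[valid] / neigh_cnt[valid])

    n = np.zeros(n_levels)
    s = np.zeros(n_levels)
    lev_v = levels[valid]
    np.add.at(n, lev_v - 1, 1.0)
    np.add.at(s, lev_v - 1, diffs[valid])
    return n, s


def ngtdm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("NGTDM requires a nonempty mask")
    levels, mask = crop_to_mask(np.asarray(levels, dtype=float), mask)
    n_levels = int(levels[mask].max())
    n, s = ngtdm_table(levels.astype(np.int64), mask, n_levels)

    nvp = n.sum()
    if nvp == 0:
        raise ValueError("no voxel has any in-mask neighbor")
    p = n / nvp
    i = np.arange(1, n_levels + 1, dtype=float)
    present = p > 0
    ngp = int(present.sum())

    sum_ps = float(np.sum(p * s))
    coarseness = 1.0 / sum_ps if sum_ps > 0 else _COARSENESS_CAP

    if ngp > 1:
        pi = p[present]
        ip = i[present]
        si = s[present]
        d2 = (ip[:, None] - ip[None, :]) ** 2
        contrast = float(
            np.sum(pi[:, None] * pi[None, :] * d2) / (ngp * (ngp - 1)) * (s.sum() / nvp)
        )
        denom_busy = float(np.sum(np.abs((ip * pi)[:, None] - (ip * pi)[None, :])))
        busyness = sum_ps / denom_busy if denom_busy > 0 else 0.0
        absdiff = np.abs(ip[:, None] - ip[None, :])
        complexity = float(
            np.sum(
                absdiff
                * (pi[:, None] * si[:, None] + pi[None, :] * si[None, :])
                / (pi[:, None] + pi[None, :])
            )
            / nvp
        )
        strength_num = float(np.sum((pi[:, None] + pi[None, :]) * d2))
        strength = strength_num / s.sum() if s.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
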
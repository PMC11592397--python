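"""Shared helpers for texture-matrix feature families."""

from __future__ import annotations

import numpy as np

# The 13 unique direction offsets covering all 26 neighbors of a voxel up to
# sign (each offset and its negation describe the same undirected direction).
ANGLES_13: tuple[tuple[int, int, int], ...] = tuple(
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a > 0) or (a == 0 and b > 0) or (a == 0 and b == 0 and c > 0)
)

STRUCT26 = np.ones((3, 3, 3), dtype=bool)

EPS = np.finfo(float).eps


def crop_to_mask(levels: np.ndarray, mask: np.ndarray, pad: int = 0):
    """Crop both arrays to the mask bounding box (plus optional padding)."""
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + pad, mask.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return levels[sl], mask[sl]


def shifted_views(arr: np.ndarray, offset: tuple[int, int, int]):
    """Aligned views (base, shifted) such that shifted[v] == arr[v + offset]."""
    slices_a, slices_b = [], []
    for n, d in zip(arr.shape, offset):
        if d == 0:
            slices_a.append(slice(0, n))
            slices_b.append(slice(0, n))
        elif d > 0:
            slices_a.append(slice(0, n - d))
            slices_b.append(slice(d, n))
        else:
            slices_a.append(slice(-d, n))
            slices_b.append(slice(0, n + d))
    return arr[tuple(slices_a)], arr[tuple(slices_b)]


def xlogx2(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with 0*log(0) = 0."""
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out
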
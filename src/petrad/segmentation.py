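"""Lesion contour variants: SUVmax-relative thresholds plus two manual-style surrogates.

Five variants per lesion: three fixed-threshold contours at 35/40/45% of the
lesion SUVmax, a CT-perception surrogate (the true lesion support when known,
else the seed region) and a PET-perception surrogate (a seeded stochastic
perturbation of the 40% contour).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .core import Volume

__all__ = [
    "MaskSet",
    "MASK_LABELS",
    "lesion_suvmax",
    "threshold_contour",
    "make_mask_set",
    "dice",
]

MASK_LABELS = ("ct_perception", "pet_perception", "suv35", "suv40", "suv45")

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class MaskSet:
    """The five contour variants of one lesion, on the volume's grid."""

    variants: dict[str, np.ndarray]
    suv_max: float
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if set(self.variants) != set(MASK_LABELS):
            raise ValueError(
                f"mask set labels must be exactly {MASK_LABELS}, got {sorted(self.variants)}"
            )
        shapes = {m.shape for m in self.variants.values()}
        if len(shapes) != 1:
            raise ValueError(f"mask variants on different grids: {shapes}")
        for label, m in self.variants.items():
            if not m.any():
                raise ValueError(f"contour variant {label!r} is empty")

    def __getitem__(self, label: str) -> np.ndarray:
        return self.variants[label]

    def counts(self) -> dict[str, int]:
        return {k: int(v.sum()) for k, v in self.variants.items()}


def lesion_suvmax(volume: Volume, seed_mask: np.ndarray) -> float:
    """Maximum uptake over the seed region."""
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if seed_mask.shape != volume.values.shape:
        raise ValueError("seed mask shape does not match volume")
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    return float(volume.values[seed_mask].max())


def _select_component(candidate: np.ndarray, seed_mask: np.ndarray) -> np.ndarray:
    """Largest 26-connected component of `candidate` intersecting the seed.

    Ties on size broken by greater seed overlap, then by lexicographically
    smallest centroid.
    """
    labels, n = ndi.label(candidate, structure=_STRUCT26)
    if n == 0:
        return np.zeros_like(candidate, dtype=bool)
    best = None
    best_key = None
    for lab in range(1, n + 1):
        comp = labels == lab
        overlap = int(np.logical_and(comp, seed_mask).sum())
        if overlap == 0:
            continue
        size = int(comp.sum())
        centroid = tuple(-c for c in np.argwhere(comp).mean(axis=0))
        key = (size, overlap, centroid)
        if best_key is None or key > best_key:
            best_key, best = key, comp
    if best is None:
        return np.zeros_like(candidate, dtype=bool)
    return best


def threshold_contour(volume: Volume, seed_mask: np.ndarray, fraction: float) -> np.ndarray:
    """Contour at ``value >= fraction * SUVmax``, one connected component.

    Returns the largest 26-connected component of the thresholded set that
    intersects the seed region.  The comparison is closed (``>=``).
    """
    if not (0 < fraction < 1):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    suv_max = lesion_suvmax(volume, seed_mask)
    cutoff = fraction * suv_max
    mask = _select_component(volume.values >= cutoff, np.asarray(seed_mask, dtype=bool))
    if not mask.any():
        raise ValueError(f"threshold contour empty at fraction {fraction} (cutoff {cutoff:.3g})")
    return mask


def _pet_perception_surrogate(
    suv40: np.ndarray, seed_mask: np.ndarray, rng: np.random.Generator, flip_prob: float = 0.2
) -> np.ndarray:
    """Blur-like perturbation of the 40% contour: dilate one voxel, then flip
    boundary voxels off with probability `flip_prob` (seeded, deterministic)."""
    dilated = ndi.binary_dilation(suv40, structure=_STRUCT26)
    eroded = ndi.binary_erosion(dilated, structure=_STRUCT26)
    boundary = dilated & ~eroded
    flips = rng.random(int(boundary.sum())) < flip_prob
    out = dilated.copy()
    out[tuple(np.argwhere(boundary)[flips].T)] = False
    out |= seed_mask  # never lose the seed core
    return _select_component(out, seed_mask)


def make_mask_set(
    volume: Volume,
    seed_mask: np.ndarray,
    true_mask: np.ndarray | None = None,
    fractions: tuple[float, float, float] = (0.35, 0.40, 0.45),
    surrogate_seed: int = 0,
) -> MaskSet:
    """Build all five contour variants for one lesion.

    ``ct_perception`` is the ground-truth support when provided (else the seed
    region); ``pet_perception`` is a seeded stochastic perturbation of the 40%
    contour; ``suv35/40/45`` are threshold contours.  Threshold variants nest:
    higher fractions give subsets.
    """
    seed_mask = np.asarray(seed_mask, dtype=bool)
    suv_max = lesion_suvmax(volume, seed_mask)
    f35, f40, f45 = sorted(fractions)
    thr = {
        "suv35": threshold_contour(volume, seed_mask, f35),
        "suv40": threshold_contour(volume, seed_mask, f40),
        "suv45": threshold_contour(volume, seed_mask, f45),
    }
    rng = np.random.default_rng(surrogate_seed)
    variants = dict(thr)
    variants["ct_perception"] = (
        np.asarray(true_mask, dtype=bool) if true_mask is not None else seed_mask.copy()
    )
    variants["pet_perception"] = _pet_perception_surrogate(thr["suv40"], seed_mask, rng)
    return MaskSet(
        variants=variants,
        suv_max=suv_max,
        spacing_mm=volume.spacing_mm,
        origin_mm=volume.origin_mm,
    )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / float(denom)
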
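"""Image filters and resampling: trilinear resampling, one-level 3D Haar DWT,
and scale-normalized Laplacian-of-Gaussian filtering."""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import ndimage as ndi

from ..core import Volume

__all__ = [
    "resample_volume",
    "wavelet_decompose",
    "wavelet_subband_mask",
    "log_filter",
    "WAVELET_SUBBANDS",
]

log = logging.getLogger(__name__)

WAVELET_SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

_WAVELET_TAPS = {
    # orthonormal analysis low-pass taps; high-pass by quadrature mirror
    "haar": np.array([1.0, 1.0]) / math.sqrt(2.0),
}


def resample_volume(
    volume: Volume,
    mask: np.ndarray | None,
    target_spacing_mm: tuple[float, float, float],
) -> tuple[Volume, np.ndarray | None]:
    """Resample to a new spacing: trilinear for intensities, nearest for the mask.

    The grid of voxel centers spans the same physical extent (within one
    voxel); origin is preserved.
    """
    target = tuple(float(s) for s in target_spacing_mm)
    if any(s <= 0 for s in target):
        raise ValueError(f"target spacing must be positive, got {target}")
    src = volume.spacing_mm
    shape = volume.values.shape
    new_shape = tuple(
        max(1, int(math.floor((n - 1) * s / t + 1e-9)) + 1)
        for n, s, t in zip(shape, src, target)
    )
    grids = [
        np.arange(new_shape[a]) * target[a] / src[a]  # fractional source indices
        for a in range(3)
    ]
    coords = np.meshgrid(*grids, indexing="ij")
    coords = np.stack([c.ravel() for c in coords])
    vals = ndi.map_coordinates(
        volume.values.astype(float), coords, order=1, mode="nearest"
    ).reshape(new_shape)
    out_vol = Volume(vals, target, volume.origin_mm)
    out_mask = None
    if mask is not None:
        out_mask = (
            ndi.map_coordinates(
                np.asarray(mask, dtype=np.uint8), coords, order=0, mode="nearest"
            )
            .reshape(new_shape)
            .astype(bool)
        )
        if not out_mask.any():
            raise ValueError("mask is empty after resampling")
    return out_vol, out_mask


def _dwt_axis(arr: np.ndarray, axis: int, taps: np.ndarray):
    """One-level DWT along one axis; odd lengths are edge-padded to even."""
    arr = np.moveaxis(arr, axis, 0)
    if arr.shape[0] % 2 == 1:
        arr = np.concatenate([arr, arr[-1:]], axis=0)
    even = arr[0::2]
    odd = arr[1::2]
    lo = taps[0] * even + taps[1] * odd
    hi = taps[1] * even - taps[0] * odd
    return np.moveaxis(lo, 0, axis), np.moveaxis(hi, 0, axis)


def wavelet_decompose(values: np.ndarray, wavelet_name: str = "haar") -> dict[str, np.ndarray]:
    """One-level separable 3D DWT; returns the 8 subbands keyed LLL..HHH.

    For even axis lengths the transform is orthonormal, so
    ``sum ||subband||^2 == ||values||^2`` (Parseval).  Odd axes are
    edge-padded to even length first.
    """
    if wavelet_name not in _WAVELET_TAPS:
        raise ValueError(
            f"unsupported wavelet {wavelet_name!r}; available: {sorted(_WAVELET_TAPS)}"
        )
    values = np.asarray(values, dtype=float)
    if any(n < 2 for n in values.shape):
        raise ValueError(f"each axis must have length >= 2, got shape {values.shape}")
    taps = _WAVELET_TAPS[wavelet_name]
    bands = {"": values}
    for axis in range(3):
        new_bands = {}
        for label, arr in bands.items():
            lo, hi = _dwt_axis(arr, axis, taps)
            new_bands[label + "L"] = lo
            new_bands[label + "H"] = hi
        bands = new_bands
    return {k: bands[k] for k in WAVELET_SUBBANDS}


def wavelet_subband_mask(mask: np.ndarray) -> np.ndarray:
    """Downsample a mask to the subband grid: a coarse voxel is in-mask when
    any of its (up to) 8 fine voxels is."""
    m = np.asarray(mask, dtype=bool)
    for axis in range(3):
        m = np.moveaxis(m, axis, 0)
        if m.shape[0] % 2 == 1:
            m = np.concatenate([m, m[-1:]], axis=0)
        m = m[0::2] | m[1::2]
        m = np.moveaxis(m, 0, axis)
    return m


def log_filter(volume: Volume, sigma_mm: float) -> Volume:
    """Scale-normalized Laplacian of Gaussian at physical scale ``sigma_mm``.

    Implemented as ``sigma^2 * sum_a d^2/dx_a^2 G_sigma * I`` with per-axis
    voxel sigmas, so anisotropic spacing is handled in physical units.
    Response on a constant field is identically zero.
    """
    if sigma_mm <= 0:
        raise ValueError(f"sigma_mm must be > 0, got {sigma_mm}")
    if sigma_mm < min(volume.spacing_mm) / 2.0:
        log.warning(
            "LoG sigma %.3g mm is below half the smallest voxel size %.3g mm; "
            "the filter is under-resolved",
            sigma_mm,
            min(volume.spacing_mm),
        )
    vals = volume.values.astype(float)
    out = np.zeros_like(vals)
    for axis in range(3):
        sp = volume.spacing_mm[axis]
        d2 = _gauss_d2_taps(sigma_mm / sp)
        smoothed = _presmooth(vals, volume.spacing_mm, sigma_mm, axis)
        out += ndi.correlate1d(smoothed, d2, axis=axis, mode="reflect") / sp**2
    return Volume(sigma_mm**2 * out, volume.spacing_mm, volume.origin_mm)


def _gauss_d2_taps(sigma_vox: float, truncate: float = 4.0) -> np.ndarray:
    """Sampled Gaussian second-derivative taps, adjusted to sum exactly to
    zero so the response to a constant field vanishes identically."""
    radius = max(1, int(truncate * sigma_vox + 0.5))
    x = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-(x**2) / (2.0 * sigma_vox**2))
    g /= g.sum()
    d2 = (x**2 - sigma_vox**2) / sigma_vox**4 * g
    return d2 - d2.sum() / d2.size


def _presmooth(vals: np.ndarray, spacing: tuple[float, float, float], sigma_mm: float, axis: int):
    """Gaussian-smooth along the axes other than `axis` (separable LoG)."""
    out = vals
    for a in range(3):
        if a == axis:
            continue
        out = ndi.gaussian_filter1d(out, sigma=sigma_mm / spacing[a], axis=a, mode="reflect")
    return out
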
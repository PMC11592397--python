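"""Core domain types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Volume"]


@dataclass
class Volume:
    """A 3D scalar image with physical geometry.

    ``values`` is indexed ``(i, j, k)``; ``spacing_mm[a]`` is the physical
    voxel size along axis ``a`` and ``origin_mm[a]`` the physical coordinate
    of voxel ``(0, 0, 0)`` along that axis.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.spacing_mm) != 3 or len(self.origin_mm) != 3:
            raise ValueError("spacing_mm and origin_mm must have length 3")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def axis_coords_mm(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis."""
        n = self.values.shape[axis]
        return self.origin_mm[axis] + self.spacing_mm[axis] * np.arange(n)

    def same_grid(self, other: "Volume", atol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=atol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=atol)
        )
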
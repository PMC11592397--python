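"""Feature extraction orchestration: image variants x feature classes -> named vector."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..core import Volume
from .discretize import discretize
from .filters import (
    WAVELET_SUBBANDS,
    log_filter,
    resample_volume,
    wavelet_decompose,
    wavelet_subband_mask,
)
from .firstorder import FIRSTORDER_NAMES, firstorder_features
from .glcm import GLCM_NAMES, glcm_features
from .gldm import GLDM_NAMES, gldm_features
from .glrlm import GLRLM_NAMES, glrlm_features
from .glszm import GLSZM_NAMES, glszm_features
from .ngtdm import NGTDM_NAMES, ngtdm_features
from .shape import SHAPE_NAMES, shape_features

__all__ = [
    "ExtractionConfig",
    "FeatureVector",
    "extract_all",
    "feature_schema",
    "default_parameter_grid",
    "ALL_CLASSES",
]

ALL_CLASSES = ("firstorder", "shape", "glcm", "glrlm", "glszm", "ngtdm", "gldm")

_CLASS_NAMES = {
    "firstorder": FIRSTORDER_NAMES,
    "shape": SHAPE_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "ngtdm": NGTDM_NAMES,
    "gldm": GLDM_NAMES,
}


@dataclass(frozen=True)
class ExtractionConfig:
    """One extraction-parameter set (bin width, resampling, filter bank)."""

    bin_width: float = 25.0
    resample: bool = False
    target_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    wavelet_name: str = "haar"
    log_sigmas_mm: tuple[float, ...] = (2.0, 4.0)
    feature_classes: tuple[str, ...] = ALL_CLASSES
    use_wavelet: bool = True
    config_id: str = ""

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError(f"bin_width must be > 0, got {self.bin_width}")
        if any(s <= 0 for s in self.log_sigmas_mm):
            raise ValueError("LoG sigmas must be positive")
        if not self.feature_classes:
            raise ValueError("feature_classes must be nonempty")
        unknown = set(self.feature_classes) - set(ALL_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")

    def image_types(self) -> list[str]:
        out = ["original"]
        out += [f"log-sigma-{s:g}mm" for s in self.log_sigmas_mm]
        if self.use_wavelet:
            out += [f"wavelet-{b}" for b in WAVELET_SUBBANDS]
        return out


@dataclass
class FeatureVector:
    """Ordered named feature values for one (subject, mask, config)."""

    names: list[str]
    values: np.ndarray
    config: ExtractionConfig
    mask_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValueError("names/values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names are not unique")
        if not np.all(np.isfinite(self.values)):
            bad = [n for n, v in zip(self.names, self.values) if not np.isfinite(v)]
            raise ValueError(f"non-finite feature values: {bad[:5]}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))

    def __len__(self) -> int:
        return len(self.names)


def feature_schema(config: ExtractionConfig) -> list[str]:
    """Deterministic feature name order for a config (shape on original only)."""
    names: list[str] = []
    intensity_classes = [c for c in ALL_CLASSES if c in config.feature_classes and c != "shape"]
    for img in config.image_types():
        for cls in intensity_classes:
            names += [f"{img}_{cls}_{feat}" for feat in _CLASS_NAMES[cls]]
        if img == "original" and "shape" in config.feature_classes:
            names += [f"original_shape_{feat}" for feat in SHAPE_NAMES]
    return names


def _intensity_features(
    values: np.ndarray,
    mask: np.ndarray,
    classes: list[str],
    bin_width: float,
    voxel_volume: float,
    img: str,
) -> dict[str, float]:
    out: dict[str, float] = {}
    levels = None
    for cls in classes:
        try:
            if cls == "firstorder":
                feats = firstorder_features(values, mask, bin_width, voxel_volume)
            else:
                if levels is None:
                    levels = np.zeros(mask.shape, dtype=np.int64)
                    levels[mask] = discretize(values[mask], bin_width)
                if cls == "glcm":
                    feats = glcm_features(levels, mask)
                elif cls == "glrlm":
                    feats = glrlm_features(levels, mask)
                elif cls == "glszm":
                    feats = glszm_features(levels, mask)
                elif cls == "ngtdm":
                    feats = ngtdm_features(levels, mask)
                elif cls == "gldm":
                    feats = gldm_features(levels, mask)
                else:  # pragma: no cover
                    raise ValueError(cls)
        except ValueError as exc:
            raise ValueError(f"failed computing {img}_{cls}: {exc}") from exc
        out.update({f"{img}_{cls}_{k}": v for k, v in feats.items()})
    return out


def extract_all(volume: Volume, mask: np.ndarray, config: ExtractionConfig) -> FeatureVector:
    """Extract the full configured feature vector for one volume/mask pair.

    Resampling (if enabled) happens first; filtered-image variants are built
    on the (possibly resampled) grid; each variant is discretized within the
    mask independently.  Shape features are computed once, on the original
    mask geometry.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.values.shape:
        raise ValueError("mask shape does not match volume")
    if not mask.any():
        raise ValueError("mask is empty")
    if config.resample:
        volume, mask = resample_volume(volume, mask, config.target_spacing_mm)

    voxel_volume = volume.voxel_volume_mm3()
    intensity_classes = [
        c for c in ALL_CLASSES if c in config.feature_classes and c != "shape"
    ]
    result: dict[str, float] = {}

    # original
    result.update(
        _intensity_features(
            volume.values.astype(float), mask, intensity_classes, config.bin_width,
            voxel_volume, "original",
        )
    )
    if "shape" in config.feature_classes:
        feats = shape_features(mask, volume.spacing_mm)
        result.update({f"original_shape_{k}": v for k, v in feats.items()})

    # LoG variants
    for sigma in config.log_sigmas_mm:
        img = f"log-sigma-{sigma:g}mm"
        filtered = log_filter(volume, sigma)
        result.update(
            _intensity_features(
                filtered.values, mask, intensity_classes, config.bin_width, voxel_volume, img
            )
        )

    # wavelet subbands (decimated grid; mask block-reduced by OR)
    if config.use_wavelet:
        bands = wavelet_decompose(volume.values, config.wavelet_name)
        sub_mask = wavelet_subband_mask(mask)
        sub_voxvol = voxel_volume * 8.0
        for band in WAVELET_SUBBANDS:
            img = f"wavelet-{band}"
            result.update(
                _intensity_features(
                    bands[band], sub_mask, intensity_classes, config.bin_width, sub_voxvol, img
                )
            )

    names = feature_schema(config)
    return FeatureVector(names=names, values=np.array([result[n] for n in names]), config=config)


def default_parameter_grid(
    bin_widths: tuple[float, ...] = (5.0, 25.0, 75.0),
    target_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    **kwargs,
) -> list[ExtractionConfig]:
    """The six extraction-parameter sets: three bin widths x with/without resampling."""
    configs = []
    for bw in bin_widths:
        for resample in (False, True):
            suffix = "rs" if resample else "orig"
            configs.append(
                ExtractionConfig(
                    bin_width=bw,
                    resample=resample,
                    target_spacing_mm=target_spacing_mm,
                    config_id=f"bw{bw:g}_{suffix}",
                    **kwargs,
                )
            )
    return configs
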
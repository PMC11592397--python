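"""First-order intensity statistics (18 features).

Computed on the raw intensities inside the mask; the two histogram features
(Entropy, Uniformity) use the fixed-bin-width discretization.
"""

from __future__ import annotations

import numpy as np

from .discretize import discretize

__all__ = ["firstorder_features", "FIRSTORDER_NAMES"]

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "Percentile10",
    "Percentile90",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def firstorder_features(
    values: np.ndarray,
    mask: np.ndarray,
    bin_width: float = 25.0,
    voxel_volume_mm3: float = 1.0,
) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("first-order features require a nonempty mask")
    x = np.asarray(values, dtype=float)[mask]
    n = x.size

    levels = discretize(x, bin_width)
    counts = np.bincount(levels)[1:]
    p = counts[counts > 0] / n

    mean = float(x.mean())
    var = float(x.var())  # population variance
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    sub = x[(x >= p10) & (x <= p90)]
    if var > 0:
        centered = x - mean
        skew = float(np.mean(centered**3) / var**1.5)
        kurt = float(np.mean(centered**4) / var**2)
    else:
        # degenerate distribution: third/fourth standardized moments undefined
        skew = 0.0
        kurt = 0.0

    energy = float(np.sum(x**2))
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume_mm3 * energy,
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(sub - sub.mean()))) if sub.size else 0.0,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float(np.sum(p**2)),
    }
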
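"""Feature-robustness screening with ICC(2,1).

Each feature is measured for every subject under every perturbation ("rater"):
six extraction-parameter sets, or five contour variants.  The two-way random
effects, absolute agreement, single-measurement intraclass correlation

    ICC(2,1) = (MS_R - MS_E) / (MS_R + (K-1) MS_E + (K/N) (MS_C - MS_E))

screens features at a strict ``ICC > threshold`` cut; the two perturbation
families are screened independently and the robust sets intersected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ICCResult",
    "icc21",
    "screen",
    "screen_summary",
    "intersect_robust",
    "feature_tensor",
]

DEFAULT_THRESHOLD = 0.75


@dataclass
class ICCResult:
    feature: str
    icc: float
    ms_r: float
    ms_c: float
    ms_e: float
    robust: bool
    degenerate: bool = False


def icc21(matrix: np.ndarray, feature: str = "", threshold: float = DEFAULT_THRESHOLD) -> ICCResult:
    """ICC(2,1) of an ``n subjects x k raters`` complete two-way layout.

    All-equal layouts are degenerate (zero total variance) and defined as
    perfectly reproducible, ICC = 1.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError(f"expected a 2D matrix, got ndim={m.ndim}")
    n, k = m.shape
    if n < 3 or k < 2:
        raise ValueError(f"need n >= 3 subjects and k >= 2 raters, got {n} x {k}")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix contains non-finite values (complete layout required)")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_r = k * np.sum((row_means - grand) ** 2)
    ss_c = n * np.sum((col_means - grand) ** 2)
    ss_t = np.sum((m - grand) ** 2)
    ss_e = max(ss_t - ss_r - ss_c, 0.0)
    ms_r = ss_r / (n - 1)
    ms_c = ss_c / (k - 1)
    ms_e = ss_e / ((n - 1) * (k - 1))

    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if ss_t == 0 or denom == 0:
        return ICCResult(feature, 1.0, ms_r, ms_c, ms_e, robust=1.0 > threshold, degenerate=True)
    icc = (ms_r - ms_e) / denom
    return ICCResult(feature, float(icc), float(ms_r), float(ms_c), float(ms_e), bool(icc > threshold))


def feature_tensor(table: pd.DataFrame, subject_col: str, rater_col: str) -> dict[str, np.ndarray]:
    """Pivot a long feature table into per-feature ``n x k`` matrices.

    ``table`` has one row per (subject, rater) and one column per feature.
    Raises if the two-way layout is incomplete.
    """
    feature_cols = [c for c in table.columns if c not in (subject_col, rater_col)]
    out = {}
    for feat in feature_cols:
        wide = table.pivot(index=subject_col, columns=rater_col, values=feat)
        if wide.isna().any().any():
            missing = int(wide.isna().sum().sum())
            raise ValueError(f"incomplete layout for feature {feat!r}: {missing} missing cells")
        out[feat] = wide.to_numpy(dtype=float)
    return out

def screen(
    tensors: dict[str, np.ndarray], threshold: float = DEFAULT_THRESHOLD
) -> tuple[list[str], pd.DataFrame]:
    """Screen every feature; returns (robust feature list, per-feature ICC table)."""
    results = [icc21(mat, feature=name, threshold=threshold) for name, mat in tensors.items()]
    table = pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "icc": [r.icc for r in results],
            "ms_r": [r.ms_r for r in results],
            "ms_c": [r.ms_c for r in results],
            "ms_e": [r.ms_e for r in results],
            "robust": [r.robust for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )
    robust = [r.feature for r in results if r.robust]
    return robust, table


def screen_summary(robust_count: int, total: int) -> dict:
    """Count/percentage summary as reported: percentage = 100*count/total, 1 decimal."""
    if total <= 0 or robust_count < 0 or robust_count > total:
        raise ValueError(f"invalid counts: {robust_count}/{total}")
    return {
        "robust_count": int(robust_count),
        "total": int(total),
        "percentage": round(100.0 * robust_count / total, 1),
    }


def intersect_robust(set_params: list[str], set_contours: list[str]) -> list[str]:
    """Features robust to both perturbation families, order preserved from the first list."""
    contour_set = set(set_contours)
    final = [f for f in set_params if f in contour_set]
    if not final:
        raise ValueError(
            "no feature is robust to both perturbation families; "
            "consider relaxing the ICC threshold"
        )
    return final
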
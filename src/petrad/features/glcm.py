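"""Gray-level co-occurrence matrix features (24 features).

Counts are accumulated separately for each of the 13 unique 3D directions at
the configured distance, symmetrized and normalized per direction; feature
values are computed per direction and averaged.
"""

from __future__ import annotations

import numpy as np

from ._util import ANGLES_13, crop_to_mask, shifted_views, xlogx2

__all__ = ["glcm_features", "glcm_matrix", "GLCM_NAMES"]

GLCM_NAMES = (
    "Autocorrelation",
    "JointAverage",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)


def glcm_matrix(
    levels: np.ndarray,
    mask: np.ndarray,
    offset: tuple[int, int, int],
    n_levels: int,
    symmetric: bool = True,
) -> np.ndarray:
    """Symmetrized, normalized co-occurrence matrix for one direction offset."""
    lev_a, lev_b = shifted_views(levels, offset)
    m_a, m_b = shifted_views(mask, offset)
    valid = m_a & m_b
    i = lev_a[valid] - 1
    j = lev_b[valid] - 1
    P = np.zeros((n_levels, n_levels), dtype=float)
    np.add.at(P, (i, j), 1.0)
    if symmetric:
        P = P + P.T
    total = P.sum()
    if total > 0:
        P /= total
    return P


def _features_from_matrix(P: np.ndarray) -> dict[str, float]:
    ng = P.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    ux = float(np.sum(i * px))
    uy = float(np.sum(i * py))
    sx = float(np.sqrt(np.sum((i - ux) ** 2 * px)))
    sy = float(np.sqrt(np.sum((i - uy) ** 2 * py)))

    # diagonal-band distributions p_{x+y}, p_{x-y}
    ks = np.arange(2, 2 * ng + 1)
    p_sum = np.zeros(ks.size)
    np.add.at(p_sum, (ii + jj).ravel() - 2, P.ravel())
    kd = np.arange(0, ng)
    p_diff = np.zeros(kd.size)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), P.ravel())

    autocorr = float(np.sum(P * ii * jj))
    contrast = float(np.sum(P * (ii - jj) ** 2))
    joint_entropy = float(-np.sum(xlogx2(P)))
    hx = float(-np.sum(xlogx2(px)))
    hy = float(-np.sum(xlogx2(py)))
    pxpy = np.outer(px, py)
    nz = (P > 0) & (pxpy > 0)
    hxy1 = float(-np.sum(P[nz] * np.log2(pxpy[nz])))
    hxy2 = float(-np.sum(xlogx2(pxpy)))

    if hx == 0 and hy == 0:
        imc1 = 0.0
    else:
        imc1 = (joint_entropy - hxy1) / max(hx, hy)
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)))))

    diff_avg = float(np.sum(kd * p_diff))

    if sx > 0 and sy > 0:
        correlation = (autocorr - ux * uy) / (sx * sy)
    else:
        correlation = 1.0  # degenerate single-level matrix: perfectly correlated

    # MCC: second largest eigenvalue of Q(i,j) = sum_k P(i,k) P(j,k) / (px_i py_k)
    keep = px > 0
    if keep.sum() <= 1:
        mcc = 1.0
    else:
        Pk = P[np.ix_(keep, keep)]
        pxk = px[keep]
        pyk = py[keep]
        Q = (Pk / pxk[:, None]) @ (Pk / pyk[None, :]).T
        eig = np.sort(np.real(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(0.0, eig[-2])))

    return {
        "Autocorrelation": autocorr,
        "JointAverage": ux,
        "ClusterProminence": float(np.sum(P * (ii + jj - ux - uy) ** 4)),
        "ClusterShade": float(np.sum(P * (ii + jj - ux - uy) ** 3)),
        "ClusterTendency": float(np.sum(P * (ii + jj - ux - uy) ** 2)),
        "Contrast": contrast,
        "Correlation": float(correlation),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-np.sum(xlogx2(p_diff))),
        "DifferenceVariance": float(np.sum((kd - diff_avg) ** 2 * p_diff)),
        "Id": float(np.sum(p_diff / (1.0 + kd))),
        "Idm": float(np.sum(p_diff / (1.0 + kd**2))),
        "Idmn": float(np.sum(p_diff / (1.0 + kd**2 / ng**2))),
        "Idn": float(np.sum(p_diff / (1.0 + kd / ng))),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": float(np.sum(p_diff[1:] / kd[1:] ** 2)) if ng > 1 else 0.0,
        "JointEnergy": float(np.sum(P**2)),
        "JointEntropy": joint_entropy,
        "MCC": mcc,
        "MaximumProbability": float(P.max()),
        "SumAverage": float(np.sum(ks * p_sum)),
        "SumEntropy": float(-np.sum(xlogx2(p_sum))),
        "SumSquares": float(np.sum(P * (ii - ux) ** 2)),
    }


def glcm_features(
    levels: np.ndarray,
    mask: np.ndarray,
    distances: tuple[int, ...] = (1,),
    symmetric: bool = True,
) -> dict[str, float]:
    """Direction-averaged GLCM features over the 13 unique 3D offsets."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("GLCM requires a nonempty mask")
    levels, mask = crop_to_mask(np.asarray(levels), mask)
    n_levels = int(levels[mask].max())

    per_direction: list[dict[str, float]] = []
    for dist in distances:
        for angle in ANGLES_13:
            offset = tuple(int(a * dist) for a in angle)
            P = glcm_matrix(levels, mask, offset, n_levels, symmetric=symmetric)
            if P.sum() == 0:
                continue  # no voxel pairs along this direction
            per_direction.append(_features_from_matrix(P))
    if not per_direction:
        raise ValueError("no co-occurring voxel pairs in any direction")
    return {
        name: float(np.mean([d[name] for d in per_direction])) for name in GLCM_NAMES
    }
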
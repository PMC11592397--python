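"""Independent brute-force oracles used by the test suite.

Everything here is written with plain Python loops and dictionaries,
deliberately avoiding the vectorized implementation paths it is used to
check.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

DIRECTIONS_13 = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a > 0) or (a == 0 and b > 0) or (a == 0 and b == 0 and c > 0)
]

NEIGHBORS_26 = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
]


def _in_bounds(v, shape):
    return all(0 <= v[a] < shape[a] for a in range(3))


def _voxels(mask):
    return [tuple(int(c) for c in v) for v in np.argwhere(mask)]


def _log2(x):
    return math.log2(x)


# --------------------------------------------------------------- GLCM

def glcm_oracle(levels, mask, ng):
    """Per-direction symmetric normalized co-occurrence matrices by pair enumeration."""
    shape = mask.shape
    matrices = []
    for d in DIRECTIONS_13:
        counts = defaultdict(float)
        for v in _voxels(mask):
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if _in_bounds(w, shape) and mask[w]:
                i, j = int(levels[v]), int(levels[w])
                counts[(i, j)] += 1.0
                counts[(j, i)] += 1.0  # symmetrize
        total = sum(counts.values())
        if total == 0:
            continue
        P = np.zeros((ng, ng))
        for (i, j), c in counts.items():
            P[i - 1, j - 1] = c / total
        matrices.append(P)
    return matrices


def glcm_contrast_oracle(levels, mask, ng):
    vals = []
    for P in glcm_oracle(levels, mask, ng):
        s = 0.0
        for i in range(ng):
            for j in range(ng):
                s += P[i, j] * (i - j) ** 2
        vals.append(s)
    return sum(vals) / len(vals)


# --------------------------------------------------------------- GLRLM

def glrlm_matrices_oracle(levels, mask, ng):
    """Per-direction run-length matrices by exhaustive run enumeration."""
    shape = mask.shape
    out = []
    for d in DIRECTIONS_13:
        runs = defaultdict(float)  # (gray, length) -> count
        seen = set()
        for v in _voxels(mask):
            if v in seen:
                continue
            g = int(levels[v])
            # walk to the start of this run
            start = v
            prev = (start[0] - d[0], start[1] - d[1], start[2] - d[2])
            while _in_bounds(prev, shape) and mask[prev] and int(levels[prev]) == g:
                start = prev
                prev = (start[0] - d[0], start[1] - d[1], start[2] - d[2])
            # walk forward collecting the run
            length = 0
            cur = start
            while _in_bounds(cur, shape) and mask[cur] and int(levels[cur]) == g:
                seen.add(cur)
                length += 1
                cur = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
            runs[(g, length)] += 1.0
        seen.clear()
        max_len = max(l for (_, l) in runs)
        P = np.zeros((ng, max_len))
        for (g, l), c in runs.items():
            P[g - 1, l - 1] = c
        out.append(P)
    return out


# --------------------------------------------------------------- GLSZM

def glszm_matrix_oracle(levels, mask, ng):
    """Zone matrix via BFS flood fill with 26-connectivity."""
    shape = mask.shape
    visited = set()
    zones = defaultdict(float)  # (gray, size) -> count
    for v in _voxels(mask):
        if v in visited:
            continue
        g = int(levels[v])
        stack = [v]
        visited.add(v)
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for d in NEIGHBORS_26:
                w = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                if (
                    w not in visited
                    and _in_bounds(w, shape)
                    and mask[w]
                    and int(levels[w]) == g
                ):
                    visited.add(w)
                    stack.append(w)
        zones[(g, size)] += 1.0
    max_size = max(s for (_, s) in zones)
    P = np.zeros((ng, max_size))
    for (g, s), c in zones.items():
        P[g - 1, s - 1] = c
    return P


# --------------------------------------------------------------- NGTDM

def ngtdm_oracle(levels, mask, ng):
    """(n_i, s_i) by explicit neighborhood enumeration."""
    shape = mask.shape
    n = [0.0] * ng
    s = [0.0] * ng
    for v in _voxels(mask):
        neigh = []
        for d in NEIGHBORS_26:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if _in_bounds(w, shape) and mask[w]:
                neigh.append(int(levels[w]))
        if not neigh:
            continue
        g = int(levels[v])
        n[g - 1] += 1.0
        s[g - 1] += abs(g - sum(neigh) / len(neigh))
    return np.array(n), np.array(s)


# --------------------------------------------------------------- GLDM

def gldm_matrix_oracle(levels, mask, ng, alpha=0.0):
    """Dependence matrix (center-inclusive sizes) by neighbor enumeration."""
    shape = mask.shape
    deps = defaultdict(float)
    max_dep = 1
    for v in _voxels(mask):
        g = int(levels[v])
        d_count = 1  # center voxel
        for d in NEIGHBORS_26:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if _in_bounds(w, shape) and mask[w] and abs(int(levels[w]) - g) <= alpha:
                d_count += 1
        deps[(g, d_count)] += 1.0
        max_dep = max(max_dep, d_count)
    P = np.zeros((ng, max_dep))
    for (g, dc), c in deps.items():
        P[g - 1, dc - 1] = c
    return P


# --------------------------------------------------------------- generic matrix features

def rl_style_features_oracle(P, n_voxels, kind):
    """Loop-based run-length-style features from a (gray x size) matrix.

    ``kind`` selects the naming convention: 'glrlm', 'glszm' or 'gldm'.
    """
    ng, ns = P.shape
    nr = 0.0
    for i in range(ng):
        for j in range(ns):
            nr += P[i, j]
    pg = [sum(P[i, j] for j in range(ns)) for i in range(ng)]
    ps = [sum(P[i, j] for i in range(ng)) for j in range(ns)]
    mu_i = sum((i + 1) * pg[i] for i in range(ng)) / nr
    mu_s = sum((j + 1) * ps[j] for j in range(ns)) / nr

    def total(fn):
        return sum(
            P[i, j] * fn(i + 1, j + 1) for i in range(ng) for j in range(ns)
        )

    entropy = 0.0
    for i in range(ng):
        for j in range(ns):
            p = P[i, j] / nr
            if p > 0:
                entropy -= p * _log2(p)

    feats = {
        "small": total(lambda i, s: 1.0 / s**2) / nr,
        "large": total(lambda i, s: s**2) / nr,
        "gln": sum(v**2 for v in pg) / nr,
        "sn": sum(v**2 for v in ps) / nr,
        "snn": sum(v**2 for v in ps) / nr**2,
        "glv": total(lambda i, s: (i - mu_i) ** 2) / nr,
        "sv": total(lambda i, s: (s - mu_s) ** 2) / nr,
        "entropy": entropy,
        "lgl": total(lambda i, s: 1.0 / i**2) / nr,
        "hgl": total(lambda i, s: i**2) / nr,
        "sl": total(lambda i, s: 1.0 / (i**2 * s**2)) / nr,
        "sh": total(lambda i, s: i**2 / s**2) / nr,
        "ll": total(lambda i, s: s**2 / i**2) / nr,
        "lh": total(lambda i, s: i**2 * s**2) / nr,
        "glnn": sum(v**2 for v in pg) / nr**2,
        "percentage": nr / n_voxels,
    }
    names = {
        "glrlm": {
            "ShortRunEmphasis": "small", "LongRunEmphasis": "large",
            "GrayLevelNonUniformity": "gln", "GrayLevelNonUniformityNormalized": "glnn",
            "RunLengthNonUniformity": "sn", "RunLengthNonUniformityNormalized": "snn",
            "RunPercentage": "percentage", "GrayLevelVariance": "glv",
            "RunVariance": "sv", "RunEntropy": "entropy",
            "LowGrayLevelRunEmphasis": "lgl", "HighGrayLevelRunEmphasis": "hgl",
            "ShortRunLowGrayLevelEmphasis": "sl", "ShortRunHighGrayLevelEmphasis": "sh",
            "LongRunLowGrayLevelEmphasis": "ll", "LongRunHighGrayLevelEmphasis": "lh",
        },
        "glszm": {
            "SmallAreaEmphasis": "small", "LargeAreaEmphasis": "large",
            "GrayLevelNonUniformity": "gln", "GrayLevelNonUniformityNormalized": "glnn",
            "SizeZoneNonUniformity": "sn", "SizeZoneNonUniformityNormalized": "snn",
            "ZonePercentage": "percentage", "GrayLevelVariance": "glv",
            "ZoneVariance": "sv", "ZoneEntropy": "entropy",
            "LowGrayLevelZoneEmphasis": "lgl", "HighGrayLevelZoneEmphasis": "hgl",
            "SmallAreaLowGrayLevelEmphasis": "sl", "SmallAreaHighGrayLevelEmphasis": "sh",
            "LargeAreaLowGrayLevelEmphasis": "ll", "LargeAreaHighGrayLevelEmphasis": "lh",
        },
        "gldm": {
            "SmallDependenceEmphasis": "small", "LargeDependenceEmphasis": "large",
            "GrayLevelNonUniformity": "gln", "DependenceNonUniformity": "sn",
            "DependenceNonUniformityNormalized": "snn", "GrayLevelVariance": "glv",
            "DependenceVariance": "sv", "DependenceEntropy": "entropy",
            "LowGrayLevelEmphasis": "lgl", "HighGrayLevelEmphasis": "hgl",
            "SmallDependenceLowGrayLevelEmphasis": "sl",
            "SmallDependenceHighGrayLevelEmphasis": "sh",
            "LargeDependenceLowGrayLevelEmphasis": "ll",
            "LargeDependenceHighGrayLevelEmphasis": "lh",
        },
    }[kind]
    return {feat: feats[key] for feat, key in names.items()}


# --------------------------------------------------------------- ICC

def icc21_oracle(matrix):
    """ICC(2,1) from explicit two-way ANOVA sums of squares (loop arithmetic)."""
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    grand = sum(m[i, j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(m[i, j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(m[i, j] for i in range(n)) / n for j in range(k)]
    ss_r = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_c = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_t = sum((m[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_e = ss_t - ss_r - ss_c
    ms_r = ss_r / (n - 1)
    ms_c = ss_c / (k - 1)
    ms_e = ss_e / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom == 0:
        return 1.0
    return (ms_r - ms_e) / denom


# --------------------------------------------------------------- Cox score oracle

def cox_newton_oracle(x, time, event, lo=-20.0, hi=20.0, tol=1e-12):
    """Solve the 1-parameter Cox score equation by bisection (no ties assumed)."""
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)

    def score(beta):
        s = 0.0
        for i in range(len(x)):
            if event[i] != 1:
                continue
            risk = [j for j in range(len(x)) if time[j] >= time[i]]
            w = [math.exp(beta * x[j]) for j in risk]
            s += x[i] - sum(wj * x[j] for wj, j in zip(w, risk)) / sum(w)
        return s

    f_lo, f_hi = score(lo), score(hi)
    if f_lo * f_hi > 0:
        raise ValueError("score equation has no root in bracket")
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if score(mid) * f_lo > 0:
            lo = mid
            f_lo = score(lo)
        else:
            hi = mid
    return (lo + hi) / 2.0


def cindex_pairs_oracle(time, event, scores):
    """All-pairs Harrell's C (ordered-pair enumeration, sksurv convention)."""
    num = 0.0
    den = 0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if i == j or event[i] != 1:
                continue
            if time[i] < time[j] or (time[i] == time[j] and event[j] == 0):
                den += 1
                if scores[i] > scores[j]:
                    num += 1.0
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


# --------------------------------------------------------------- GLCM features

def _glcm_features_single(P):
    ng = P.shape[0]
    px = [sum(P[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(P[i, j] for i in range(ng)) for j in range(ng)]
    ux = sum((i + 1) * px[i] for i in range(ng))
    uy = sum((j + 1) * py[j] for j in range(ng))
    sx = math.sqrt(sum((i + 1 - ux) ** 2 * px[i] for i in range(ng)))
    sy = math.sqrt(sum((j + 1 - uy) ** 2 * py[j] for j in range(ng)))
    p_sum = defaultdict(float)
    p_diff = defaultdict(float)
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j + 2] += P[i, j]
            p_diff[abs(i - j)] += P[i, j]

    def ent(probs):
        return -sum(p * _log2(p) for p in probs if p > 0)

    autocorr = sum(P[i, j] * (i + 1) * (j + 1) for i in range(ng) for j in range(ng))
    joint_entropy = ent(P.ravel())
    hx, hy = ent(px), ent(py)
    hxy1 = -sum(
        P[i, j] * _log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if P[i, j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = ent([px[i] * py[j] for i in range(ng) for j in range(ng)])
    imc1 = 0.0 if (hx == 0 and hy == 0) else (joint_entropy - hxy1) / max(hx, hy)
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - joint_entropy))))
    da = sum(k * v for k, v in p_diff.items())

    keep = [i for i in range(ng) if px[i] > 0]
    if len(keep) <= 1:
        mcc = 1.0
    else:
        Q = np.zeros((len(keep), len(keep)))
        for a, i in enumerate(keep):
            for b, j in enumerate(keep):
                Q[a, b] = sum(
                    P[i, k] * P[j, k] / (px[i] * py[k]) for k in keep if py[k] > 0
                )
        eig = sorted(np.real(np.linalg.eigvals(Q)))
        mcc = math.sqrt(max(0.0, eig[-2]))

    corr = 1.0 if sx == 0 or sy == 0 else (autocorr - ux * uy) / (sx * sy)
    return {
        "Autocorrelation": autocorr,
        "JointAverage": ux,
        "ClusterProminence": sum(
            P[i, j] * (i + j + 2 - ux - uy) ** 4 for i in range(ng) for j in range(ng)
        ),
        "ClusterShade": sum(
            P[i, j] * (i + j + 2 - ux - uy) ** 3 for i in range(ng) for j in range(ng)
        ),
        "ClusterTendency": sum(
            P[i, j] * (i + j + 2 - ux - uy) ** 2 for i in range(ng) for j in range(ng)
        ),
        "Contrast": sum(P[i, j] * (i - j) ** 2 for i in range(ng) for j in range(ng)),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(p_diff.values()),
        "DifferenceVariance": sum((k - da) ** 2 * v for k, v in p_diff.items()),
        "Id": sum(v / (1.0 + k) for k, v in p_diff.items()),
        "Idm": sum(v / (1.0 + k**2) for k, v in p_diff.items()),
        "Idmn": sum(v / (1.0 + k**2 / ng**2) for k, v in p_diff.items()),
        "Idn": sum(v / (1.0 + k / ng) for k, v in p_diff.items()),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": (
            sum(v / k**2 for k, v in p_diff.items() if k >= 1) if ng > 1 else 0.0
        ),
        "JointEnergy": sum(P[i, j] ** 2 for i in range(ng) for j in range(ng)),
        "JointEntropy": joint_entropy,
        "MCC": mcc,
        "MaximumProbability": P.max(),
        "SumAverage": sum(k * v for k, v in p_sum.items()),
        "SumEntropy": ent(p_sum.values()),
        "SumSquares": sum(
            P[i, j] * (i + 1 - ux) ** 2 for i in range(ng) for j in range(ng)
        ),
    }


def glcm_features_oracle(levels, mask, ng):
    per_dir = [_glcm_features_single(P) for P in glcm_oracle(levels, mask, ng)]
    return {
        name: sum(d[name] for d in per_dir) / len(per_dir) for name in per_dir[0]
    }


def glrlm_features_oracle(levels, mask, ng):
    n_voxels = int(mask.sum())
    per_dir = [
        rl_style_features_oracle(P, n_voxels, "glrlm")
        for P in glrlm_matrices_oracle(levels, mask, ng)
    ]
    return {
        name: sum(d[name] for d in per_dir) / len(per_dir) for name in per_dir[0]
    }


def ngtdm_features_oracle(levels, mask, ng):
    n, s = ngtdm_oracle(levels, mask, ng)
    nvp = sum(n)
    p = [ni / nvp for ni in n]
    present = [i for i in range(ng) if p[i] > 0]
    ngp = len(present)
    sum_ps = sum(p[i] * s[i] for i in range(ng))
    coarseness = 1.0 / sum_ps if sum_ps > 0 else 1e6
    if ngp > 1:
        contrast = (
            sum(
                p[i] * p[j] * (i - j) ** 2
                for i in present
                for j in present
            )
            / (ngp * (ngp - 1))
            * (sum(s) / nvp)
        )
        denom_busy = sum(
            abs((i + 1) * p[i] - (j + 1) * p[j]) for i in present for j in present
        )
        busyness = sum_ps / denom_busy if denom_busy > 0 else 0.0
        complexity = (
            sum(
                abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                for i in present
                for j in present
            )
            / nvp
        )
        strength_num = sum(
            (p[i] + p[j]) * (i - j) ** 2 for i in present for j in present
        )
        strength = strength_num / sum(s) if sum(s) > 0 else 0.0
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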
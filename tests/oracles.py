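"""Independent brute-force oracles for texture features.

Everything here is written as plain loops that transcribe the matrix and
feature definitions directly, with no shared code with the package's
vectorized implementations.  Intended for small ROIs (tens of voxels).
"""

from __future__ import annotations

import itertools
import math

import numpy as np

DIRECTIONS = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

NEIGHBOURS_26 = [
    d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
]


def _in_bounds(p, shape):
    return all(0 <= p[a] < shape[a] for a in range(3))


def glcm_brute(levels: np.ndarray, direction, n_levels: int) -> np.ndarray:
    P = np.zeros((n_levels, n_levels))
    shape = levels.shape
    for p in itertools.product(*(range(s) for s in shape)):
        if levels[p] == 0:
            continue
        q = tuple(p[a] + direction[a] for a in range(3))
        if _in_bounds(q, shape) and levels[q] > 0:
            P[levels[p] - 1, levels[q] - 1] += 1
            P[levels[q] - 1, levels[p] - 1] += 1
    return P


def glrlm_brute(levels: np.ndarray, direction, n_levels: int) -> np.ndarray:
    """Enumerate maximal equal-level runs along one direction."""
    shape = levels.shape
    runs = []
    for p in itertools.product(*(range(s) for s in shape)):
        if levels[p] == 0:
            continue
        prev = tuple(p[a] - direction[a] for a in range(3))
        if _in_bounds(prev, shape) and levels[prev] == levels[p]:
            continue  # not a run start
        length = 1
        q = tuple(p[a] + direction[a] for a in range(3))
        while _in_bounds(q, shape) and levels[q] == levels[p]:
            length += 1
            q = tuple(q[a] + direction[a] for a in range(3))
        runs.append((levels[p], length))
    max_len = max(l for _, l in runs)
    R = np.zeros((n_levels, max_len))
    for g, l in runs:
        R[g - 1, l - 1] += 1
    return R


def glszm_brute(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Flood-fill 26-connected equal-level zones."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for p in itertools.product(*(range(s) for s in shape)):
        if levels[p] == 0 or seen[p]:
            continue
        g = levels[p]
        stack, size = [p], 0
        seen[p] = True
        while stack:
            cur = stack.pop()
            size += 1
            for d in NEIGHBOURS_26:
                q = tuple(cur[a] + d[a] for a in range(3))
                if _in_bounds(q, shape) and not seen[q] and levels[q] == g:
                    seen[q] = True
                    stack.append(q)
        zones.append((g, size))
    max_size = max(s for _, s in zones)
    Z = np.zeros((n_levels, max_size))
    for g, s in zones:
        Z[g - 1, s - 1] += 1
    return Z


def ngtdm_brute(levels: np.ndarray, n_levels: int):
    shape = levels.shape
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for p in itertools.product(*(range(s) for s in shape)):
        if levels[p] == 0:
            continue
        nbr = [
            levels[tuple(p[a] + d[a] for a in range(3))]
            for d in NEIGHBOURS_26
            if _in_bounds(tuple(p[a] + d[a] for a in range(3)), shape)
        ]
        nbr = [v for v in nbr if v > 0]
        if not nbr:
            continue
        n_i[levels[p] - 1] += 1
        s_i[levels[p] - 1] += abs(levels[p] - sum(nbr) / len(nbr))
    return n_i, s_i


def gldm_brute(levels: np.ndarray, n_levels: int, alpha: float = 0.0) -> np.ndarray:
    shape = levels.shape
    recs = []
    for p in itertools.product(*(range(s) for s in shape)):
        if levels[p] == 0:
            continue
        dep = 1
        for d in NEIGHBOURS_26:
            q = tuple(p[a] + d[a] for a in range(3))
            if _in_bounds(q, shape) and levels[q] > 0 and abs(levels[q] - levels[p]) <= alpha:
                dep += 1
        recs.append((levels[p], dep))
    max_dep = max(d for _, d in recs)
    D = np.zeros((n_levels, max_dep))
    for g, d in recs:
        D[g - 1, d - 1] += 1
    return D


# ---------------------------------------------------------------------------
# feature formulas, transcribed with explicit loops

def glcm_features_brute(P: np.ndarray) -> dict[str, float] | None:
    ng = P.shape[0]
    total = P.sum()
    if total == 0:
        return None
    p = P / total
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    sig_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng)))
    sig_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng)))

    pxmy = [0.0] * ng
    pxpy = [0.0] * (2 * ng - 1)
    for i in range(ng):
        for j in range(ng):
            pxmy[abs(i - j)] += p[i][j]
            pxpy[i + j] += p[i][j]

    def h(vals):
        return -sum(v * math.log2(v) for v in vals if v > 0)

    autoc = sum(p[i][j] * (i + 1) * (j + 1) for i in range(ng) for j in range(ng))
    da = sum(k * pxmy[k] for k in range(ng))
    hxy = h(p.ravel())
    hxy1 = -sum(
        p[i][j] * math.log2(px[i] * py[j])
        for i in range(ng) for j in range(ng)
        if p[i][j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = h([px[i] * py[j] for i in range(ng) for j in range(ng)])
    hx, hy = h(px), h(py)
    out = {
        "glcm_Autocorrelation": autoc,
        "glcm_JointAverage": mu_x,
        "glcm_ClusterProminence": sum(
            p[i][j] * (i + j + 2 - mu_x - mu_y) ** 4 for i in range(ng) for j in range(ng)
        ),
        "glcm_ClusterShade": sum(
            p[i][j] * (i + j + 2 - mu_x - mu_y) ** 3 for i in range(ng) for j in range(ng)
        ),
        "glcm_ClusterTendency": sum(
            p[i][j] * (i + j + 2 - mu_x - mu_y) ** 2 for i in range(ng) for j in range(ng)
        ),
        "glcm_Contrast": sum(
            p[i][j] * (i - j) ** 2 for i in range(ng) for j in range(ng)
        ),
        "glcm_Correlation": (
            (autoc - mu_x * mu_y) / (sig_x * sig_y) if sig_x > 0 and sig_y > 0 else 1.0
        ),
        "glcm_DifferenceAverage": da,
        "glcm_DifferenceEntropy": h(pxmy),
        "glcm_DifferenceVariance": sum(
            pxmy[k] * (k - da) ** 2 for k in range(ng)
        ),
        "glcm_JointEnergy": sum(
            p[i][j] ** 2 for i in range(ng) for j in range(ng)
        ),
        "glcm_JointEntropy": hxy,
        "glcm_Imc1": (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0,
        "glcm_Imc2": math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))),
        "glcm_Idm": sum(
            p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)
        ),
        "glcm_Idmn": sum(
            p[i][j] / (1 + ((i - j) / ng) ** 2) for i in range(ng) for j in range(ng)
        ),
        "glcm_Id": sum(
            p[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)
        ),
        "glcm_Idn": sum(
            p[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
        ),
        "glcm_InverseVariance": sum(
            p[i][j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
        ),
        "glcm_MaximumProbability": p.max(),
        "glcm_SumAverage": sum((k + 2) * pxpy[k] for k in range(2 * ng - 1)),
        "glcm_SumEntropy": h(pxpy),
        "glcm_SumSquares": sum(
            p[i][j] * (i + 1 - mu_x) ** 2 for i in range(ng) for j in range(ng)
        ),
    }
    return out


def _size_features_brute(M: np.ndarray, n_voxels: int) -> dict[str, float]:
    ng, nc = M.shape
    nz = M.sum()
    p = M / nz
    mu_i = sum(p[i][j] * (i + 1) for i in range(ng) for j in range(nc))
    mu_j = sum(p[i][j] * (j + 1) for i in range(ng) for j in range(nc))
    return {
        "SmallEmphasis": sum(M[i][j] / (j + 1) ** 2 for i in range(ng) for j in range(nc)) / nz,
        "LargeEmphasis": sum(M[i][j] * (j + 1) ** 2 for i in range(ng) for j in range(nc)) / nz,
        "GrayLevelNonUniformity": sum(M[i].sum() ** 2 for i in range(ng)) / nz,
        "GrayLevelNonUniformityNormalized": sum(M[i].sum() ** 2 for i in range(ng)) / nz**2,
        "SizeNonUniformity": sum(M[:, j].sum() ** 2 for j in range(nc)) / nz,
        "SizeNonUniformityNormalized": sum(M[:, j].sum() ** 2 for j in range(nc)) / nz**2,
        "Percentage": nz / n_voxels,
        "GrayLevelVariance": sum(
            p[i][j] * (i + 1 - mu_i) ** 2 for i in range(ng) for j in range(nc)
        ),
        "SizeVariance": sum(
            p[i][j] * (j + 1 - mu_j) ** 2 for i in range(ng) for j in range(nc)
        ),
        "Entropy": -sum(
            p[i][j] * math.log2(p[i][j]) for i in range(ng) for j in range(nc) if p[i][j] > 0
        ),
        "LowGrayLevelEmphasis": sum(
            M[i][j] / (i + 1) ** 2 for i in range(ng) for j in range(nc)
        ) / nz,
        "HighGrayLevelEmphasis": sum(
            M[i][j] * (i + 1) ** 2 for i in range(ng) for j in range(nc)
        ) / nz,
        "SmallLow": sum(
            M[i][j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ng) for j in range(nc)
        ) / nz,
        "SmallHigh": sum(
            M[i][j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(ng) for j in range(nc)
        ) / nz,
        "LargeLow": sum(
            M[i][j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for j in range(nc)
        ) / nz,
        "LargeHigh": sum(
            M[i][j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(ng) for j in range(nc)
        ) / nz,
    }


_GLRLM_MAP = {
    "SmallEmphasis": "glrlm_ShortRunEmphasis",
    "LargeEmphasis": "glrlm_LongRunEmphasis",
    "GrayLevelNonUniformity": "glrlm_GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "glrlm_GrayLevelNonUniformityNormalized",
    "SizeNonUniformity": "glrlm_RunNonUniformity",
    "SizeNonUniformityNormalized": "glrlm_RunNonUniformityNormalized",
    "Percentage": "glrlm_RunPercentage",
    "GrayLevelVariance": "glrlm_GrayLevelVariance",
    "SizeVariance": "glrlm_RunVariance",
    "Entropy": "glrlm_RunEntropy",
    "LowGrayLevelEmphasis": "glrlm_LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis": "glrlm_HighGrayLevelEmphasis",
    "SmallLow": "glrlm_ShortRunLowGrayLevelEmphasis",
    "SmallHigh": "glrlm_ShortRunHighGrayLevelEmphasis",
    "LargeLow": "glrlm_LongRunLowGrayLevelEmphasis",
    "LargeHigh": "glrlm_LongRunHighGrayLevelEmphasis",
}

_GLSZM_MAP = {
    "SmallEmphasis": "glszm_SmallAreaEmphasis",
    "LargeEmphasis": "glszm_LargeAreaEmphasis",
    "GrayLevelNonUniformity": "glszm_GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "glszm_GrayLevelNonUniformityNormalized",
    "SizeNonUniformity": "glszm_ZoneNonUniformity",
    "SizeNonUniformityNormalized": "glszm_ZoneNonUniformityNormalized",
    "Percentage": "glszm_ZonePercentage",
    "GrayLevelVariance": "glszm_GrayLevelVariance",
    "SizeVariance": "glszm_ZoneVariance",
    "Entropy": "glszm_ZoneEntropy",
    "LowGrayLevelEmphasis": "glszm_LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis": "glszm_HighGrayLevelEmphasis",
    "SmallLow": "glszm_SmallAreaLowGrayLevelEmphasis",
    "SmallHigh": "glszm_SmallAreaHighGrayLevelEmphasis",
    "LargeLow": "glszm_LargeAreaLowGrayLevelEmphasis",
    "LargeHigh": "glszm_LargeAreaHighGrayLevelEmphasis",
}

_GLDM_MAP = {
    "SmallEmphasis": "gldm_SmallDependenceEmphasis",
    "LargeEmphasis": "gldm_LargeDependenceEmphasis",
    "GrayLevelNonUniformity": "gldm_GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "gldm_GrayLevelNonUniformityNormalized",
    "SizeNonUniformity": "gldm_DependenceNonUniformity",
    "SizeNonUniformityNormalized": "gldm_DependenceNonUniformityNormalized",
    "Percentage": "gldm_DependencePercentage",
    "GrayLevelVariance": "gldm_GrayLevelVariance",
    "SizeVariance": "gldm_DependenceVariance",
    "Entropy": "gldm_DependenceEntropy",
    "LowGrayLevelEmphasis": "gldm_LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis": "gldm_HighGrayLevelEmphasis",
    "SmallLow": "gldm_SmallDependenceLowGrayLevelEmphasis",
    "SmallHigh": "gldm_SmallDependenceHighGrayLevelEmphasis",
    "LargeLow": "gldm_LargeDependenceLowGrayLevelEmphasis",
    "LargeHigh": "gldm_LargeDependenceHighGrayLevelEmphasis",
}


def ngtdm_features_brute(n_i, s_i) -> dict[str, float]:
    nvp = n_i.sum()
    p = [v / nvp for v in n_i]
    idx = [i for i in range(len(p)) if p[i] > 0]
    ngp = len(idx)
    ps = sum(p[i] * s_i[i] for i in idx)
    coarseness = 1.0 / ps if ps > 0 else 1e6
    if ngp > 1:
        contrast = sum(
            p[i] * p[j] * (i - j) ** 2 for i in idx for j in idx
        ) / (ngp * (ngp - 1)) * sum(s_i) / nvp
        denom = sum(abs((i + 1) * p[i] - (j + 1) * p[j]) for i in idx for j in idx)
        busyness = ps / denom if denom > 0 else 0.0
        complexity = sum(
            abs(i - j) * (p[i] * s_i[i] + p[j] * s_i[j]) / (p[i] + p[j])
            for i in idx for j in idx
        ) / nvp
        s_sum = sum(s_i)
        strength = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in idx for j in idx) / s_sum
            if s_sum > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "ngtdm_Coarseness": coarseness,
        "ngtdm_Contrast": contrast,
        "ngtdm_Busyness": busyness,
        "ngtdm_Complexity": complexity,
        "ngtdm_Strength": strength,
    }


def texture_features_brute(levels: np.ndarray, n_voxels: int) -> dict[str, float]:
    """All matrix-class features on a quantized ROI array (0 = outside)."""
    n_levels = int(levels.max())
    out: dict[str, float] = {}

    per_dir = [glcm_features_brute(glcm_brute(levels, d, n_levels)) for d in DIRECTIONS]
    per_dir = [f for f in per_dir if f is not None]
    for k in per_dir[0]:
        out[k] = float(np.mean([f[k] for f in per_dir]))

    rl_dir = []
    for d in DIRECTIONS:
        feats = _size_features_brute(glrlm_brute(levels, d, n_levels), n_voxels)
        rl_dir.append({_GLRLM_MAP[k]: v for k, v in feats.items()})
    for k in rl_dir[0]:
        out[k] = float(np.mean([f[k] for f in rl_dir]))

    sz = _size_features_brute(glszm_brute(levels, n_levels), n_voxels)
    out.update({_GLSZM_MAP[k]: v for k, v in sz.items()})

    out.update(ngtdm_features_brute(*ngtdm_brute(levels, n_levels)))

    dm = _size_features_brute(gldm_brute(levels, n_levels), n_voxels)
    out.update({_GLDM_MAP[k]: v for k, v in dm.items()})
    return out
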
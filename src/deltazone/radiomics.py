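"""Texture feature extraction on dose-zone ROIs, and paired-scan change
features.

The extraction follows the IBSI conventions for original-image features:
intensities are z-normalized over a reference region (the lungs), the ROI is
discretized at a fixed bin width anchored at the ROI minimum, and seven
feature classes are computed in 3-D — shape, first-order, grey-level
co-occurrence (GLCM), run length (GLRLM), size zone (GLSZM), neighbourhood
grey-tone difference (NGTDM) and dependence (GLDM).  GLCM and GLRLM use
distance 1 with the 13 unique 3-D directions and report the mean over
directions; GLSZM/GLDM/NGTDM use the 26-connected neighbourhood.

Longitudinal change is expressed per feature as a percent delta between the
planning scan and the mid-treatment resetting scan:

    dRF = (RF_CT2 - RF_CT1) / RF_CT1 * 100

Entries whose baseline value is numerically zero are flagged undefined and
excluded downstream rather than silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import ImageVolume, ROIMask

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "DeltaFeatureVector",
    "znormalize",
    "discretize",
    "extract_features",
    "delta_features",
    "ALL_CLASSES",
]

ALL_CLASSES = ("shape", "firstorder", "glcm", "glrlm", "glszm", "ngtdm", "gldm")

# 13 unique 3-D directions at Chebyshev distance 1 (the other 13 of the 26
# neighbours are their negatives; co-occurrence is symmetrized instead).
DIRECTIONS_3D = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)



@dataclass(frozen=True)
class FeatureConfig:
    """Extraction settings: which classes to compute and the discretization
    bin width (intensity units of the normalized image)."""

    classes: tuple[str, ...] = ALL_CLASSES
    bin_width: float = 25.0

    def __post_init__(self) -> None:
        unknown = set(self.classes) - set(ALL_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        object.__setattr__(self, "classes", tuple(self.classes))


@dataclass
class FeatureVector:
    """Named feature values for one (subject, zone, timepoint)."""

    values: dict[str, float]
    subject: str | None = None
    zone_label: str | None = None
    timepoint: str | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite feature values: {bad[:5]}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class DeltaFeatureVector:
    """Percent change per feature between two timepoints; entries that are
    undefined (baseline ~ 0) are listed separately, never imputed."""

    values: dict[str, float]
    undefined: tuple[str, ...] = ()
    subject: str | None = None
    zone_label: str | None = None


def znormalize(ct: ImageVolume, reference: ROIMask) -> ImageVolume:
    """Standardize CT values to zero mean / unit SD over the reference region.

    The whole image is transformed with the reference-region statistics, so
    voxel intensities stay comparable across scans and scanner offsets drop
    out before discretization.
    """
    if not ct.same_grid(reference):
        raise ValueError("image and reference mask must share a grid")
    ref = ct.data[reference.data]
    if ref.size == 0:
        raise ValueError("empty reference region")
    sd = float(ref.std())
    if sd == 0.0:
        raise ValueError("reference region has zero variance")
    return ct.with_data((ct.data - float(ref.mean())) / sd)


def discretize(ct: ImageVolume, roi: ROIMask, bin_width: float = 25.0) -> np.ndarray:
    """Fixed-bin-width quantization of ROI intensities, anchored at the ROI
    minimum: ``level(v) = floor((v - min_roi)/w) + 1``.

    Returns an integer array on the full grid with level 0 outside the ROI.
    """
    if not ct.same_grid(roi):
        raise ValueError("image and ROI must share a grid")
    if roi.voxel_count == 0:
        raise ValueError("empty ROI")
    vals = ct.data[roi.data]
    levels = np.zeros(ct.shape, dtype=np.int64)
    levels[roi.data] = np.floor((vals - vals.min()) / bin_width).astype(np.int64) + 1
    return levels


# --------------------------------------------------------------------------
# first-order and shape

def _firstorder(vals: np.ndarray, levels_in_roi: np.ndarray,
                voxel_volume: float) -> dict[str, float]:
    n = vals.size
    mean = vals.mean()
    p10, p25, p50, p75, p90 = np.percentile(vals, [10, 25, 50, 75, 90])
    hist = np.bincount(levels_in_roi)[1:].astype(float)
    p = hist[hist > 0] / n
    dev = vals - mean
    var = float(np.mean(dev**2))
    sd = np.sqrt(var)
    skew = float(np.mean(dev**3) / sd**3) if sd > 0 else 0.0
    kurt = float(np.mean(dev**4) / sd**4) if sd > 0 else 0.0
    return {
        "firstorder_Mean": float(mean),
        "firstorder_Median": float(p50),
        "firstorder_Minimum": float(vals.min()),
        "firstorder_Maximum": float(vals.max()),
        "firstorder_Range": float(vals.max() - vals.min()),
        "firstorder_10Percentile": float(p10),
        "firstorder_90Percentile": float(p90),
        "firstorder_InterquartileRange": float(p75 - p25),
        "firstorder_Variance": var,
        "firstorder_StandardDeviation": float(sd),
        "firstorder_Skewness": skew,
        "firstorder_Kurtosis": kurt,
        "firstorder_MeanAbsoluteDeviation": float(np.abs(dev).mean()),
        "firstorder_RobustMeanAbsoluteDeviation": _robust_mad(vals, p10, p90),
        "firstorder_Energy": float(np.sum(vals**2)),
        "firstorder_TotalEnergy": float(voxel_volume * np.sum(vals**2)),
        "firstorder_RootMeanSquared": float(np.sqrt(np.mean(vals**2))),
        "firstorder_Entropy": float(-np.sum(p * np.log2(p))),
        "firstorder_Uniformity": float(np.sum(p**2)),
    }


def _robust_mad(vals: np.ndarray, p10: float, p90: float) -> float:
    sel = vals[(vals >= p10) & (vals <= p90)]
    if sel.size == 0:
        return 0.0
    return float(np.abs(sel - sel.mean()).mean())


def _shape(mask: np.ndarray, spacing: tuple[float, float, float]) -> dict[str, float]:
    sx, sy, sz = spacing
    n = int(mask.sum())
    volume = n * sx * sy * sz

    # surface area by counting exposed voxel faces
    area = 0.0
    face_area = {0: sy * sz, 1: sx * sz, 2: sx * sy}
    for axis in range(3):
        pad = np.pad(mask, [(1, 1) if a == axis else (0, 0) for a in range(3)])
        diff = np.diff(pad.astype(np.int8), axis=axis)
        area += float(np.abs(diff).sum()) * face_area[axis]

    coords = np.argwhere(mask).astype(float) * np.array(spacing)
    diameter = _max_diameter(coords)
    if n > 1:
        cov = np.cov(coords, rowvar=False)
        lam = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1]
        lam = np.clip(lam, 0.0, None)
    else:
        lam = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(lam)).tolist()
    sphericity = (36.0 * np.pi * volume**2) ** (1.0 / 3.0) / area if area > 0 else 0.0
    return {
        "shape_VoxelVolume": volume,
        "shape_SurfaceArea": area,
        "shape_SurfaceVolumeRatio": area / volume if volume > 0 else 0.0,
        "shape_Sphericity": sphericity,
        "shape_Maximum3DDiameter": diameter,
        "shape_MajorAxisLength": major,
        "shape_MinorAxisLength": minor,
        "shape_LeastAxisLength": least,
        "shape_Elongation": float(np.sqrt(lam[1] / lam[0])) if lam[0] > 0 else 0.0,
        "shape_Flatness": float(np.sqrt(lam[2] / lam[0])) if lam[0] > 0 else 0.0,
    }


def _max_diameter(coords: np.ndarray) -> float:
    if len(coords) < 2:
        return 0.0
    pts = coords
    if len(coords) > 200:
        try:  # hull vertices suffice for the farthest pair
            from scipy.spatial import ConvexHull
            pts = coords[ConvexHull(coords, qhull_options="QJ").vertices]
        except Exception:
            pts = coords
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


# --------------------------------------------------------------------------
# matrix builders

def _shifted_pairs(levels: np.ndarray, d: tuple[int, int, int]):
    """Source/destination level arrays for voxel pairs at offset ``d``."""
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, step in enumerate(d):
        if step > 0:
            src[ax], dst[ax] = slice(None, -step), slice(step, None)
        elif step < 0:
            src[ax], dst[ax] = slice(-step, None), slice(None, step)
    return levels[tuple(src)], levels[tuple(dst)]


def glcm_matrix(levels: np.ndarray, d: tuple[int, int, int], n_levels: int) -> np.ndarray:
    """Symmetric grey-level co-occurrence counts for one direction."""
    a, b = _shifted_pairs(levels, d)
    valid = (a > 0) & (b > 0)
    idx = (a[valid] - 1) * n_levels + (b[valid] - 1)
    P = np.bincount(idx, minlength=n_levels * n_levels).reshape(n_levels, n_levels)
    return (P + P.T).astype(float)


def glrlm_matrix(levels: np.ndarray, d: tuple[int, int, int], n_levels: int) -> np.ndarray:
    """Run-length counts for one direction (rows: level, cols: run length)."""
    in_roi = levels > 0
    run = np.where(in_roi, 1, 0).astype(np.int64)
    # run[p] = length of the run ending at p when walking along d
    steps = max(abs(s) * n for s, n in zip(d, levels.shape))
    prev_lv, cur_lv = _shifted_pairs(levels, d)
    prev_run_view, cur_run_view = _shifted_pairs(run, d)
    for _ in range(steps):
        same = (cur_lv > 0) & (cur_lv == prev_lv)
        new = np.where(same, prev_run_view + 1, cur_run_view)
        if np.array_equal(new, cur_run_view):
            break
        cur_run_view[...] = new
    # a run ends at p where the next voxel along d differs
    nxt_same = np.zeros(levels.shape, dtype=bool)
    a, b = _shifted_pairs(levels, d)
    src = [slice(None)] * 3
    for ax, step in enumerate(d):
        if step > 0:
            src[ax] = slice(None, -step)
        elif step < 0:
            src[ax] = slice(-step, None)
    nxt_same[tuple(src)] = (a > 0) & (a == b)
    ends = in_roi & ~nxt_same
    lv = levels[ends]
    rl = run[ends]
    max_len = int(rl.max()) if rl.size else 1
    R = np.zeros((n_levels, max_len), dtype=float)
    np.add.at(R, (lv - 1, rl - 1), 1.0)
    return R


def glszm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone counts (rows: level, cols: zone size), 26-connectivity."""
    structure = np.ones((3, 3, 3), dtype=bool)
    records: list[tuple[int, int]] = []
    for g in range(1, n_levels + 1):
        lab, n_zones = ndimage.label(levels == g, structure=structure)
        if n_zones == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        records.extend((g, int(s)) for s in sizes)
    max_size = max(s for _, s in records)
    Z = np.zeros((n_levels, max_size), dtype=float)
    for g, s in records:
        Z[g - 1, s - 1] += 1.0
    return Z


def _neighbour_sums(levels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per voxel: sum of in-ROI 26-neighbour levels, and neighbour count."""
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    lv = levels.astype(float)
    in_roi = (levels > 0).astype(float)
    nbr_sum = ndimage.convolve(lv, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.convolve(in_roi, kernel, mode="constant", cval=0.0)
    return nbr_sum, np.rint(nbr_cnt)


def ngtdm_table(levels: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """NGTDM vectors: per level i, voxel count n_i and summed absolute
    difference s_i between the level and its mean neighbour level.  Voxels
    with no in-ROI neighbour are excluded."""
    nbr_sum, nbr_cnt = _neighbour_sums(levels)
    valid = (levels > 0) & (nbr_cnt > 0)
    lv = levels[valid].astype(float)
    mean_nbr = nbr_sum[valid] / nbr_cnt[valid]
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    np.add.at(n_i, levels[valid] - 1, 1.0)
    np.add.at(s_i, levels[valid] - 1, np.abs(lv - mean_nbr))
    return n_i, s_i


def gldm_matrix(levels: np.ndarray, n_levels: int, alpha: float = 0.0) -> np.ndarray:
    """Dependence counts: D[i, k] = voxels of level i+1 whose dependence is
    k+1, where dependence = 1 + number of 26-neighbours within ``alpha`` of
    the centre level."""
    in_roi = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for d in DIRECTIONS_3D:
        for sign in (1, -1):
            off = tuple(sign * s for s in d)
            a, b = _shifted_pairs(levels, off)
            src = [slice(None)] * 3
            for ax, step in enumerate(off):
                if step > 0:
                    src[ax] = slice(None, -step)
                elif step < 0:
                    src[ax] = slice(-step, None)
            close = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
            dep[tuple(src)] += close
    dep_val = dep[in_roi] + 1
    lv = levels[in_roi]
    D = np.zeros((n_levels, int(dep_val.max())), dtype=float)
    np.add.at(D, (lv - 1, dep_val - 1), 1.0)
    return D


# --------------------------------------------------------------------------
# features from matrices

def glcm_features(P: np.ndarray) -> dict[str, float]:
    s = P.sum()
    p = P / s
    ng = P.shape[0]
    i = np.arange(1, ng + 1)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    sig_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * px)))
    sig_y = float(np.sqrt(np.sum((i - mu_y) ** 2 * py)))
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = np.abs(ii - jj)

    # diagonal (difference) and cross-diagonal (sum) distributions
    pxmy = np.zeros(ng)
    np.add.at(pxmy, diff.ravel().astype(int), p.ravel())
    k_d = np.arange(ng)
    pxpy = np.zeros(2 * ng - 1)
    np.add.at(pxpy, (ii + jj - 2).ravel().astype(int), p.ravel())
    k_s = np.arange(2, 2 * ng + 1)

    autocorr = float(np.sum(p * ii * jj))
    contrast = float(np.sum(p * (ii - jj) ** 2))
    if sig_x > 0 and sig_y > 0:
        correlation = (autocorr - mu_x * mu_y) / (sig_x * sig_y)
    else:
        correlation = 1.0
    da = float(np.sum(pxmy * k_d))

    def ent(q):
        q = q[q > 0]
        return float(-np.sum(q * np.log2(q)))

    hxy = ent(p)
    hx, hy = ent(px), ent(py)
    outer = px[:, None] * py[None, :]
    nz = (p > 0) & (outer > 0)
    hxy1 = float(-np.sum(p[nz] * np.log2(outer[nz])))
    hxy2 = ent(outer)
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    off = diff > 0
    inv_var = float(np.sum(p[off] / diff[off] ** 2)) if off.any() else 0.0

    return {
        "glcm_Autocorrelation": autocorr,
        "glcm_JointAverage": mu_x,
        "glcm_ClusterProminence": float(np.sum(p * (ii + jj - mu_x - mu_y) ** 4)),
        "glcm_ClusterShade": float(np.sum(p * (ii + jj - mu_x - mu_y) ** 3)),
        "glcm_ClusterTendency": float(np.sum(p * (ii + jj - mu_x - mu_y) ** 2)),
        "glcm_Contrast": contrast,
        "glcm_Correlation": float(correlation),
        "glcm_DifferenceAverage": da,
        "glcm_DifferenceEntropy": ent(pxmy),
        "glcm_DifferenceVariance": float(np.sum(pxmy * (k_d - da) ** 2)),
        "glcm_JointEnergy": float(np.sum(p**2)),
        "glcm_JointEntropy": hxy,
        "glcm_Imc1": float(imc1),
        "glcm_Imc2": imc2,
        "glcm_Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "glcm_Idmn": float(np.sum(p / (1.0 + ((ii - jj) / ng) ** 2))),
        "glcm_Id": float(np.sum(p / (1.0 + diff))),
        "glcm_Idn": float(np.sum(p / (1.0 + diff / ng))),
        "glcm_InverseVariance": inv_var,
        "glcm_MaximumProbability": float(p.max()),
        "glcm_SumAverage": float(np.sum(pxpy * k_s)),
        "glcm_SumEntropy": ent(pxpy),
        "glcm_SumSquares": float(np.sum(p * (ii - mu_x) ** 2)),
    }


def _size_matrix_features(M: np.ndarray, n_voxels: int, prefix: str,
                          row_name: str, col_name: str) -> dict[str, float]:
    """Shared feature family for run-length / size-zone / dependence
    matrices: rows are grey levels, columns the size-like index."""
    nz = M.sum()
    p = M / nz
    ng, nc = M.shape
    i = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, nc + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    row = M.sum(axis=1)
    col = M.sum(axis=0)
    mu_i = float(np.sum(p * ii))
    mu_j = float(np.sum(p * jj))
    pnz = p[p > 0]
    return {
        f"{prefix}_Small{col_name}Emphasis": float(np.sum(M / jj**2) / nz),
        f"{prefix}_Large{col_name}Emphasis": float(np.sum(M * jj**2) / nz),
        f"{prefix}_GrayLevelNonUniformity": float(np.sum(row**2) / nz),
        f"{prefix}_GrayLevelNonUniformityNormalized": float(np.sum(row**2) / nz**2),
        f"{prefix}_{col_name}NonUniformity": float(np.sum(col**2) / nz),
        f"{prefix}_{col_name}NonUniformityNormalized": float(np.sum(col**2) / nz**2),
        f"{prefix}_{col_name}Percentage": float(nz / n_voxels),
        f"{prefix}_GrayLevelVariance": float(np.sum(p * (ii - mu_i) ** 2)),
        f"{prefix}_{col_name}Variance": float(np.sum(p * (jj - mu_j) ** 2)),
        f"{prefix}_{col_name}Entropy": float(-np.sum(pnz * np.log2(pnz))),
        f"{prefix}_LowGrayLevelEmphasis": float(np.sum(M / ii**2) / nz),
        f"{prefix}_HighGrayLevelEmphasis": float(np.sum(M * ii**2) / nz),
        f"{prefix}_Small{col_name}LowGrayLevelEmphasis": float(np.sum(M / (ii**2 * jj**2)) / nz),
        f"{prefix}_Small{col_name}HighGrayLevelEmphasis": float(np.sum(M * ii**2 / jj**2) / nz),
        f"{prefix}_Large{col_name}LowGrayLevelEmphasis": float(np.sum(M * jj**2 / ii**2) / nz),
        f"{prefix}_Large{col_name}HighGrayLevelEmphasis": float(np.sum(M * ii**2 * jj**2) / nz),
    }


def glrlm_features(R: np.ndarray, n_voxels: int) -> dict[str, float]:
    f = _size_matrix_features(R, n_voxels, "glrlm", "GrayLevel", "Run")
    ren = {
        "glrlm_SmallRunEmphasis": "glrlm_ShortRunEmphasis",
        "glrlm_LargeRunEmphasis": "glrlm_LongRunEmphasis",
        "glrlm_SmallRunLowGrayLevelEmphasis": "glrlm_ShortRunLowGrayLevelEmphasis",
        "glrlm_SmallRunHighGrayLevelEmphasis": "glrlm_ShortRunHighGrayLevelEmphasis",
        "glrlm_LargeRunLowGrayLevelEmphasis": "glrlm_LongRunLowGrayLevelEmphasis",
        "glrlm_LargeRunHighGrayLevelEmphasis": "glrlm_LongRunHighGrayLevelEmphasis",
    }
    return {ren.get(k, k): v for k, v in f.items()}


def glszm_features(Z: np.ndarray, n_voxels: int) -> dict[str, float]:
    f = _size_matrix_features(Z, n_voxels, "glszm", "GrayLevel", "Zone")
    ren = {
        "glszm_SmallZoneEmphasis": "glszm_SmallAreaEmphasis",
        "glszm_LargeZoneEmphasis": "glszm_LargeAreaEmphasis",
        "glszm_SmallZoneLowGrayLevelEmphasis": "glszm_SmallAreaLowGrayLevelEmphasis",
        "glszm_SmallZoneHighGrayLevelEmphasis": "glszm_SmallAreaHighGrayLevelEmphasis",
        "glszm_LargeZoneLowGrayLevelEmphasis": "glszm_LargeAreaLowGrayLevelEmphasis",
        "glszm_LargeZoneHighGrayLevelEmphasis": "glszm_LargeAreaHighGrayLevelEmphasis",
    }
    return {ren.get(k, k): v for k, v in f.items()}


def gldm_features(D: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _size_matrix_features(D, n_voxels, "gldm", "GrayLevel", "Dependence")


def ngtdm_features(n_i: np.ndarray, s_i: np.ndarray) -> dict[str, float]:
    nvp = n_i.sum()
    p_i = n_i / nvp
    levels = np.arange(1, len(n_i) + 1, dtype=float)
    present = p_i > 0
    ngp = int(present.sum())
    ps = float(np.sum(p_i * s_i))
    coarseness = 1.0 / ps if ps > 0 else 1e6

    if ngp > 1:
        pi_, pj_ = np.meshgrid(p_i[present], p_i[present], indexing="ij")
        li_, lj_ = np.meshgrid(levels[present], levels[present], indexing="ij")
        contrast = float(np.sum(pi_ * pj_ * (li_ - lj_) ** 2)) / (ngp * (ngp - 1))
        contrast *= float(s_i.sum()) / nvp
        denom = float(np.sum(np.abs(li_ * pi_ - lj_ * pj_)))
        busyness = ps / denom if denom > 0 else 0.0
        si_, sj_ = np.meshgrid(s_i[present], s_i[present], indexing="ij")
        complexity = float(
            np.sum(np.abs(li_ - lj_) * (pi_ * si_ + pj_ * sj_) / (pi_ + pj_))
        ) / nvp
        s_sum = float(s_i.sum())
        strength = (
            float(np.sum((pi_ + pj_) * (li_ - lj_) ** 2)) / s_sum if s_sum > 0 else 0.0
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


# --------------------------------------------------------------------------
# public extraction entry points

def extract_features(
    ct: ImageVolume,
    roi: ROIMask,
    config: FeatureConfig = FeatureConfig(),
) -> FeatureVector:
    """Compute the configured feature classes on one ROI of one scan.

    Texture classes require at least two ROI voxels.  A single-level
    (flat) ROI is legal: entropy- and contrast-type features come out 0 and
    the vector is flagged degenerate.
    """
    if not ct.same_grid(roi):
        raise ValueError("image and ROI must share a grid")
    n_vox = roi.voxel_count
    if n_vox == 0:
        raise ValueError("empty ROI")
    texture_classes = set(config.classes) & {"glcm", "glrlm", "glszm", "ngtdm", "gldm"}
    if texture_classes and n_vox < 2:
        raise ValueError("texture classes require an ROI of at least 2 voxels")

    levels = discretize(ct, roi, config.bin_width)
    roi_levels = levels[roi.data]
    n_levels = int(roi_levels.max())

    out: dict[str, float] = {}
    if "shape" in config.classes:
        out.update(_shape(roi.data, ct.spacing_mm))
    if "firstorder" in config.classes:
        out.update(_firstorder(ct.data[roi.data], roi_levels, ct.voxel_volume_mm3))
    if "glcm" in config.classes:
        per_dir = []
        for d in DIRECTIONS_3D:
            P = glcm_matrix(levels, d, n_levels)
            if P.sum() > 0:
                per_dir.append(glcm_features(P))
        out.update(_mean_over_directions(per_dir))
    if "glrlm" in config.classes:
        per_dir = [
            glrlm_features(glrlm_matrix(levels, d, n_levels), n_vox)
            for d in DIRECTIONS_3D
        ]
        out.update(_mean_over_directions(per_dir))
    if "glszm" in config.classes:
        out.update(glszm_features(glszm_matrix(levels, n_levels), n_vox))
    if "ngtdm" in config.classes:
        out.update(ngtdm_features(*ngtdm_table(levels, n_levels)))
    if "gldm" in config.classes:
        out.update(gldm_features(gldm_matrix(levels, n_levels), n_vox))

    return FeatureVector(
        values=out,
        zone_label=roi.zone_label,
        degenerate=(n_levels == 1),
    )


def _mean_over_directions(per_dir: list[dict[str, float]]) -> dict[str, float]:
    if not per_dir:
        return {}
    keys = per_dir[0].keys()
    return {k: float(np.mean([f[k] for f in per_dir])) for k in keys}


def delta_features(
    fv1: FeatureVector,
    fv2: FeatureVector,
    eps: float = 1e-12,
) -> DeltaFeatureVector:
    """Percent change of each feature from the planning scan (fv1) to the
    resetting scan (fv2): ``(RF2 - RF1)/RF1 * 100``.

    Features whose baseline magnitude falls below ``eps`` cannot be
    expressed as a percent change; they are flagged undefined and excluded
    from the downstream feature matrix.
    """
    if set(fv1.values) != set(fv2.values):
        raise ValueError("feature name sets differ between timepoints")
    if fv1.zone_label != fv2.zone_label or (
        fv1.subject is not None and fv2.subject is not None
        and fv1.subject != fv2.subject
    ):
        raise ValueError("delta requires matching subject and zone provenance")
    values: dict[str, float] = {}
    undefined: list[str] = []
    for name, rf1 in fv1.values.items():
        if abs(rf1) < eps:
            undefined.append(name)
        else:
            values[name] = (fv2.values[name] - rf1) / rf1 * 100.0
    return DeltaFeatureVector(
        values=values,
        undefined=tuple(undefined),
        subject=fv1.subject or fv2.subject,
        zone_label=fv1.zone_label,
    )
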
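"""Radiomics feature mathematics: first-order, shape and texture-matrix
features on a 3D volume restricted to a binary mask, plus the LoG and
wavelet image filters.

The texture families follow the standard gray-level matrix definitions
(co-occurrence, run length, size zone, neighbouring gray-tone difference,
dependence).  Intensities are discretized with a fixed bin width before any
texture matrix is built.  All functions are deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure

EPS = np.finfo(float).eps

# 13 unique 3D direction offsets (half of the 26-neighbourhood).
OFFSETS_13 = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

OFFSETS_26 = [o for o in OFFSETS_13] + [tuple(-x for x in o) for o in OFFSETS_13]


# ---------------------------------------------------------------------------
# discretization

def discretize(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Fixed-bin-width discretization to integer levels 1..Ng.

    Bin edges are anchored at the masked minimum; a constant region maps to
    the single level 1.
    """
    v = np.asarray(values, dtype=float)
    lo = v.min()
    levels = np.floor((v - lo) / bin_width).astype(np.int64) + 1
    return levels


# ---------------------------------------------------------------------------
# first-order statistics (18 features)

FIRSTORDER_NAMES = [
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
]


def firstorder_features(values: np.ndarray, voxel_volume: float,
                        bin_width: float) -> dict:
    x = np.asarray(values, dtype=float)
    n = x.size
    mean = x.mean()
    var = x.var()
    sd = np.sqrt(var)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    levels = discretize(x, bin_width)
    p = np.bincount(levels)[1:].astype(float)
    p = p[p > 0] / n
    robust = x[(x >= p10) & (x <= p90)]
    if sd > 0:
        skew = np.mean((x - mean) ** 3) / sd ** 3
        kurt = np.mean((x - mean) ** 4) / sd ** 4  # plain, not excess
    else:
        skew, kurt = 0.0, 0.0
    return {
        "Energy": float(np.sum(x ** 2)),
        "TotalEnergy": float(voxel_volume * np.sum(x ** 2)),
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(
            np.mean(np.abs(robust - robust.mean())) if robust.size else 0.0),
        "RootMeanSquared": float(np.sqrt(np.mean(x ** 2))),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": float(var),
        "Uniformity": float(np.sum(p ** 2)),
    }


# ---------------------------------------------------------------------------
# shape (14 features) — mask-only, intensity independent

SHAPE_NAMES = [
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
]


def _max_pairwise(coords: np.ndarray) -> float:
    if len(coords) < 2:
        return 0.0
    # O(B^2) on boundary voxels only; ROIs here are small
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def shape_features(mask: np.ndarray, spacing: tuple) -> dict:
    mask = mask.astype(bool)
    spacing = np.asarray(spacing, dtype=float)
    nv = int(mask.sum())
    voxel_volume = float(np.prod(spacing))

    padded = np.pad(mask, 1).astype(float)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5,
                                               spacing=tuple(spacing))
    surface_area = float(measure.mesh_surface_area(verts, faces))
    tri = verts[faces]
    mesh_volume = float(abs(np.einsum(
        "ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0))

    # boundary voxels: mask minus its erosion
    eroded = ndimage.binary_erosion(mask)
    boundary = mask & ~eroded
    bc = np.argwhere(boundary) * spacing
    max3d = _max_pairwise(bc)

    def max2d(axis):
        best = 0.0
        idx = np.argwhere(boundary)
        for v in np.unique(idx[:, axis]):
            sel = idx[idx[:, axis] == v]
            plane = np.delete(sel, axis, axis=1) * np.delete(spacing, axis)
            best = max(best, _max_pairwise(plane))
        return best

    coords = np.argwhere(mask) * spacing
    if nv > 1:
        cov = np.cov(coords, rowvar=False)
        eig = np.sort(np.clip(np.linalg.eigvalsh(cov), 0, None))[::-1]
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()

    sphericity = float((36 * np.pi * mesh_volume ** 2) ** (1 / 3)
                       / max(surface_area, EPS))
    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": nv * voxel_volume,
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / max(mesh_volume, EPS),
        "Sphericity": sphericity,
        "Maximum3DDiameter": max3d,
        "Maximum2DDiameterSlice": max2d(0),
        "Maximum2DDiameterColumn": max2d(2),
        "Maximum2DDiameterRow": max2d(1),
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": float(np.sqrt(eig[1] / max(eig[0], EPS))),
        "Flatness": float(np.sqrt(eig[2] / max(eig[0], EPS))),
    }


# ---------------------------------------------------------------------------
# GLCM (24 features)

GLCM_NAMES = [
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "Id", "Idm", "Idmn", "Idn",
    "Imc1", "Imc2", "InverseVariance", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
]


def _offset_slices(shape, off):
    """Slices (a, b) such that arr[b] is arr[a] shifted by `off`."""
    sl_a, sl_b = [], []
    for ax, o in enumerate(off):
        if o == 0:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
        elif o > 0:
            sl_a.append(slice(0, shape[ax] - o))
            sl_b.append(slice(o, None))
        else:
            sl_a.append(slice(-o, None))
            sl_b.append(slice(0, shape[ax] + o))
    return tuple(sl_a), tuple(sl_b)


def _shifted_pairs(lv: np.ndarray, valid: np.ndarray, off):
    """Index pairs (a, b) of levels for voxels where voxel and voxel+off are
    both inside the mask."""
    sl_a, sl_b = _offset_slices(lv.shape, off)
    ok = valid[sl_a] & valid[sl_b]
    return lv[sl_a][ok], lv[sl_b][ok]


def _glcm_single(p: np.ndarray) -> dict:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float(np.sum(ii * p))          # symmetric: mu_x == mu_y
    sig2 = float(np.sum((ii - mu) ** 2 * p))
    sig = np.sqrt(sig2)

    k_diff = np.arange(0, ng)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj - 2).ravel(), p.ravel())

    nz = p > 0
    hxy = float(-np.sum(p[nz] * np.log2(p[nz])))
    pxj = px[:, None] * px[None, :]
    nzx = pxj > 0
    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0])))
    hxy1 = float(-np.sum(p[nzx & nz] * np.log2(pxj[nzx & nz])))
    hxy2 = float(-np.sum(pxj[nzx] * np.log2(pxj[nzx])))

    da = float(np.sum(k_diff * p_diff))
    corr = 1.0 if sig2 <= EPS else float(
        (np.sum(ii * jj * p) - mu * mu) / sig2)

    # maximal correlation coefficient
    if ng > 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            q = (p / px[:, None]) @ (p / px[None, :]).T
        q = np.nan_to_num(q)
        ev = np.sort(np.abs(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(np.clip(ev[-2], 0, 1)))
    else:
        mcc = 1.0

    imc1 = 0.0 if max(hx, EPS) <= EPS or hxy == 0 else (hxy - hxy1) / max(hx, EPS)
    imc2 = float(np.sqrt(np.clip(1 - np.exp(-2.0 * (hxy2 - hxy)), 0, None)))

    off_diag = np.abs(ii - jj) > 0
    return {
        "Autocorrelation": float(np.sum(ii * jj * p)),
        "JointAverage": mu,
        "ClusterProminence": float(np.sum((ii + jj - 2 * mu) ** 4 * p)),
        "ClusterShade": float(np.sum((ii + jj - 2 * mu) ** 3 * p)),
        "ClusterTendency": float(np.sum((ii + jj - 2 * mu) ** 2 * p)),
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(
            -np.sum(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0]))),
        "DifferenceVariance": float(np.sum((k_diff - da) ** 2 * p_diff)),
        "Id": float(np.sum(p / (1 + np.abs(ii - jj)))),
        "Idm": float(np.sum(p / (1 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1 + ((ii - jj) / ng) ** 2))),
        "Idn": float(np.sum(p / (1 + np.abs(ii - jj) / ng))),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": float(
            np.sum(p[off_diag] / (ii[off_diag] - jj[off_diag]) ** 2)),
        "JointEnergy": float(np.sum(p ** 2)),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float(np.sum(k_sum * p_sum)),
        "SumEntropy": float(
            -np.sum(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0]))),
        "SumSquares": sig2,
    }


def glcm_features(levels: np.ndarray, mask: np.ndarray) -> dict:
    """Symmetric GLCM at distance 1 over the 13 unique 3D directions;
    feature values averaged over directions with a valid matrix."""
    ng = int(levels[mask].max())
    lv = np.where(mask, levels, 0)
    acc, count = {}, 0
    for off in OFFSETS_13:
        a, b = _shifted_pairs(lv, mask, off)
        if a.size == 0:
            continue
        m = np.zeros((ng, ng))
        np.add.at(m, (a - 1, b - 1), 1.0)
        m = m + m.T
        p = m / m.sum()
        feats = _glcm_single(p)
        for k, v in feats.items():
            acc[k] = acc.get(k, 0.0) + v
        count += 1
    if count == 0:          # single-voxel ROI: no pairs
        return {k: 0.0 for k in GLCM_NAMES}
    return {k: acc[k] / count for k in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM (16 features)

GLRLM_NAMES = [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]


def _runs_in_direction(lv: np.ndarray, mask: np.ndarray, off) -> tuple:
    """Vectorized run-length extraction along one direction.

    Returns (levels, lengths) of all maximal runs.  A run start is a masked
    voxel whose predecessor along the direction is outside the mask or has a
    different level; runs are then advanced front-wise, one step per
    iteration, all active runs at once.
    """
    shape = lv.shape
    idx = np.argwhere(mask)
    off = np.asarray(off)
    prev = idx - off
    inb = np.all((prev >= 0) & (prev < shape), axis=1)
    prev_c = np.clip(prev, 0, np.asarray(shape) - 1)
    prev_in_mask = mask[tuple(prev_c.T)] & inb
    prev_same = prev_in_mask & (lv[tuple(prev_c.T)] == lv[tuple(idx.T)])
    starts = idx[~prev_same]
    levels = lv[tuple(starts.T)]
    lengths = np.ones(len(starts), dtype=np.int64)
    pos = starts.copy()
    active = np.ones(len(starts), dtype=bool)
    while active.any():
        pos[active] += off
        cur = pos[active]
        inb = np.all((cur >= 0) & (cur < shape), axis=1)
        cur_c = np.clip(cur, 0, np.asarray(shape) - 1)
        same = inb & mask[tuple(cur_c.T)] & (
            lv[tuple(cur_c.T)] == levels[active])
        lengths[np.flatnonzero(active)[same]] += 1
        active[np.flatnonzero(active)[~same]] = False
    return levels, lengths


def _rl_matrix_features(p: np.ndarray, n_voxels: int, kind: str) -> dict:
    """Shared formulas for run-length (kind='Run') and size-zone
    (kind='Zone'/'Size') style matrices p[level-1, length-1] (counts)."""
    nr = p.sum()
    i = np.arange(1, p.shape[0] + 1, dtype=float)
    j = np.arange(1, p.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    pg = p.sum(axis=1)
    pr = p.sum(axis=0)
    pn = p / nr
    mu_i = np.sum(ii * pn)
    mu_j = np.sum(jj * pn)
    nzp = pn[pn > 0]
    return {
        "Short%sEmphasis": float(np.sum(p / jj ** 2) / nr),
        "Long%sEmphasis": float(np.sum(p * jj ** 2) / nr),
        "GrayLevelNonUniformity": float(np.sum(pg ** 2) / nr),
        "GrayLevelNonUniformityNormalized": float(np.sum(pg ** 2) / nr ** 2),
        "%sLengthNonUniformity": float(np.sum(pr ** 2) / nr),
        "%sLengthNonUniformityNormalized": float(np.sum(pr ** 2) / nr ** 2),
        "%sPercentage": float(nr / n_voxels),
        "GrayLevelVariance": float(np.sum((ii - mu_i) ** 2 * pn)),
        "%sVariance": float(np.sum((jj - mu_j) ** 2 * pn)),
        "%sEntropy": float(-np.sum(nzp * np.log2(nzp))),
        "LowGrayLevel%sEmphasis": float(np.sum(p / ii ** 2) / nr),
        "HighGrayLevel%sEmphasis": float(np.sum(p * ii ** 2) / nr),
        "Short%sLowGrayLevelEmphasis": float(
            np.sum(p / (ii ** 2 * jj ** 2)) / nr),
        "Short%sHighGrayLevelEmphasis": float(
            np.sum(p * ii ** 2 / jj ** 2) / nr),
        "Long%sLowGrayLevelEmphasis": float(
            np.sum(p * jj ** 2 / ii ** 2) / nr),
        "Long%sHighGrayLevelEmphasis": float(
            np.sum(p * ii ** 2 * jj ** 2) / nr),
    }


def glrlm_features(levels: np.ndarray, mask: np.ndarray) -> dict:
    ng = int(levels[mask].max())
    lv = np.where(mask, levels, 0)
    nvox = int(mask.sum())
    acc = None
    for off in OFFSETS_13:
        lvs, lens = _runs_in_direction(lv, mask, off)
        m = np.zeros((ng, int(lens.max())))
        np.add.at(m, (lvs - 1, lens - 1), 1.0)
        raw = _rl_matrix_features(m, nvox, "Run")
        feats = {k.replace("%s", "Run"): v for k, v in raw.items()}
        if acc is None:
            acc = {k: 0.0 for k in feats}
        for k, v in feats.items():
            acc[k] += v
    out = {k: acc[k] / len(OFFSETS_13) for k in acc}
    return {k: out[k] for k in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# GLSZM (16 features)

GLSZM_NAMES = [
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]

_RL_TO_SZ = {
    "ShortRunEmphasis": "SmallAreaEmphasis",
    "LongRunEmphasis": "LargeAreaEmphasis",
    "RunLengthNonUniformity": "SizeZoneNonUniformity",
    "RunLengthNonUniformityNormalized": "SizeZoneNonUniformityNormalized",
    "RunPercentage": "ZonePercentage",
    "RunVariance": "ZoneVariance",
    "RunEntropy": "ZoneEntropy",
    "LowGrayLevelRunEmphasis": "LowGrayLevelZoneEmphasis",
    "HighGrayLevelRunEmphasis": "HighGrayLevelZoneEmphasis",
    "ShortRunLowGrayLevelEmphasis": "SmallAreaLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis": "SmallAreaHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis": "LargeAreaLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis": "LargeAreaHighGrayLevelEmphasis",
}

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_features(levels: np.ndarray, mask: np.ndarray) -> dict:
    ng = int(levels[mask].max())
    lv = np.where(mask, levels, 0)
    zones_lv, zones_sz = [], []
    for g in range(1, ng + 1):
        sel = lv == g
        if not sel.any():
            continue
        lab, nlab = ndimage.label(sel, structure=_STRUCT_26)
        sizes = np.bincount(lab.ravel())[1:]
        zones_lv.extend([g] * nlab)
        zones_sz.extend(sizes.tolist())
    zones_lv = np.asarray(zones_lv)
    zones_sz = np.asarray(zones_sz)
    m = np.zeros((ng, int(zones_sz.max())))
    np.add.at(m, (zones_lv - 1, zones_sz - 1), 1.0)
    raw = _rl_matrix_features(m, int(mask.sum()), "Zone")
    out = {}
    for k, v in raw.items():
        name = k.replace("%s", "Run")
        out[_RL_TO_SZ.get(name, name)] = v
    return {k: out[k] for k in GLSZM_NAMES}


# ---------------------------------------------------------------------------
# neighbourhood accumulators shared by NGTDM / GLDM

def _neighbor_stats(lv: np.ndarray, mask: np.ndarray):
    """Per masked voxel: sum/count of 26-neighbour levels inside the mask and
    count of neighbours with identical level."""
    nsum = np.zeros(lv.shape)
    ncnt = np.zeros(lv.shape)
    nsame = np.zeros(lv.shape)
    for off in OFFSETS_26:
        sl_a, sl_b = _offset_slices(lv.shape, off)
        ok = mask[sl_b]
        nsum[sl_a] += np.where(ok, lv[sl_b], 0)
        ncnt[sl_a] += ok
        nsame[sl_a] += ok & (lv[sl_b] == lv[sl_a])
    return nsum, ncnt, nsame


NGTDM_NAMES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]


def ngtdm_features(levels: np.ndarray, mask: np.ndarray) -> dict:
    ng = int(levels[mask].max())
    lv = np.where(mask, levels, 0)
    nsum, ncnt, _ = _neighbor_stats(lv, mask)
    sel = mask & (ncnt > 0)
    li = lv[sel].astype(float)
    avg = nsum[sel] / ncnt[sel]
    diffs = np.abs(li - avg)
    nv = int(sel.sum())
    s = np.zeros(ng)
    n_i = np.zeros(ng)
    np.add.at(s, (li - 1).astype(int), diffs)
    np.add.at(n_i, (li - 1).astype(int), 1.0)
    p_i = n_i / nv
    present = p_i > 0
    i = np.arange(1, ng + 1, dtype=float)
    ngp = int(present.sum())

    coarse = 1.0 / max(float(np.sum(p_i * s)), EPS)
    if ngp > 1:
        ii, jj = np.meshgrid(i[present], i[present], indexing="ij")
        pi_, pj_ = np.meshgrid(p_i[present], p_i[present], indexing="ij")
        si_, sj_ = np.meshgrid(s[present], s[present], indexing="ij")
        contrast = (np.sum(pi_ * pj_ * (ii - jj) ** 2)
                    / (ngp * (ngp - 1))) * (np.sum(s) / nv)
        busy_den = float(np.sum(np.abs(ii * pi_ - jj * pj_)))
        busyness = float(np.sum(p_i * s)) / max(busy_den, EPS)
        complexity = float(np.sum(
            np.abs(ii - jj) * (pi_ * si_ + pj_ * sj_) / (pi_ + pj_))) / nv
        strength = float(np.sum((pi_ + pj_) * (ii - jj) ** 2)) / max(
            float(np.sum(s)), EPS)
    else:
        contrast, busyness, complexity, strength = 0.0, 0.0, 0.0, 0.0
    return {
        "Coarseness": float(coarse),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }


GLDM_NAMES = [
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
]


def gldm_features(levels: np.ndarray, mask: np.ndarray) -> dict:
    """Gray-level dependence: dependence of a voxel = 1 + number of
    26-neighbours inside the mask with the same discretized level
    (dependence tolerance alpha = 0)."""
    ng = int(levels[mask].max())
    lv = np.where(mask, levels, 0)
    _, _, nsame = _neighbor_stats(lv, mask)
    dep = (nsame[mask] + 1).astype(int)
    li = lv[mask]
    nd = int(dep.max())
    m = np.zeros((ng, nd))
    np.add.at(m, (li - 1, dep - 1), 1.0)
    nz = m.sum()
    i = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, nd + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    pn = m / nz
    pg = m.sum(axis=1)
    pd = m.sum(axis=0)
    mu_i = np.sum(ii * pn)
    mu_j = np.sum(jj * pn)
    nzp = pn[pn > 0]
    return {
        "SmallDependenceEmphasis": float(np.sum(m / jj ** 2) / nz),
        "LargeDependenceEmphasis": float(np.sum(m * jj ** 2) / nz),
        "GrayLevelNonUniformity": float(np.sum(pg ** 2) / nz),
        "DependenceNonUniformity": float(np.sum(pd ** 2) / nz),
        "DependenceNonUniformityNormalized": float(np.sum(pd ** 2) / nz ** 2),
        "GrayLevelVariance": float(np.sum((ii - mu_i) ** 2 * pn)),
        "DependenceVariance": float(np.sum((jj - mu_j) ** 2 * pn)),
        "DependenceEntropy": float(-np.sum(nzp * np.log2(nzp))),
        "LowGrayLevelEmphasis": float(np.sum(m / ii ** 2) / nz),
        "HighGrayLevelEmphasis": float(np.sum(m * ii ** 2) / nz),
        "SmallDependenceLowGrayLevelEmphasis": float(
            np.sum(m / (ii ** 2 * jj ** 2)) / nz),
        "SmallDependenceHighGrayLevelEmphasis": float(
            np.sum(m * ii ** 2 / jj ** 2) / nz),
        "LargeDependenceLowGrayLevelEmphasis": float(
            np.sum(m * jj ** 2 / ii ** 2) / nz),
        "LargeDependenceHighGrayLevelEmphasis": float(
            np.sum(m * ii ** 2 * jj ** 2) / nz),
    }


# ---------------------------------------------------------------------------
# image filters

def log_filter(volume: np.ndarray, sigma_mm: float, spacing: tuple) -> np.ndarray:
    """Laplacian-of-Gaussian with an isotropic physical sigma (mm)."""
    sig_vox = [sigma_mm / s for s in spacing]
    return ndimage.gaussian_laplace(volume.astype(float), sigma=sig_vox)


def wavelet_bands(volume: np.ndarray, wavelet: str = "coif1") -> dict:
    """Level-1 undecimated separable wavelet decomposition into the eight
    low/high octants.  Band label letter order follows axis order
    (slice, row, col); e.g. 'LLH' = low-pass on slices and rows, high-pass
    on columns."""
    import pywt

    w = pywt.Wavelet(wavelet)
    lo = np.asarray(w.dec_lo)[::-1]
    hi = np.asarray(w.dec_hi)[::-1]
    vol = volume.astype(float)
    bands = {"": vol}
    for axis in range(3):
        new = {}
        for label, arr in bands.items():
            new[label + "L"] = ndimage.convolve1d(arr, lo, axis=axis,
                                                  mode="reflect")
            new[label + "H"] = ndimage.convolve1d(arr, hi, axis=axis,
                                                  mode="reflect")
        bands = new
    return bands


TEXTURE_EXTRACTORS = {
    "GLCM": (glcm_features, GLCM_NAMES),
    "GLRLM": (glrlm_features, GLRLM_NAMES),
    "GLSZM": (glszm_features, GLSZM_NAMES),
    "NGTDM": (ngtdm_features, NGTDM_NAMES),
    "GLDM": (gldm_features, GLDM_NAMES),
}
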
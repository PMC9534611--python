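"""Gray-level texture matrices and their statistics (GLCM, GLRLM, GLSZM,
GLDM, NGTDM).

All matrices are built on the discretized 3D ROI following the standard
conventions of the radiomics literature:

* GLCM / GLRLM: 13 unique direction offsets at Chebyshev distance 1, one
  matrix per direction, statistics averaged over directions (directions with
  no valid pairs/runs are skipped).
* GLSZM: zones are 26-connected components of equal gray level.
* GLDM: dependence counts over the 26-neighbourhood with tolerance alpha=0;
  the dependence size includes the centre voxel.
* NGTDM: neighbourhood average over the 26-neighbourhood, voxels with no
  in-mask neighbour are excluded.

Degenerate single-level ROIs use documented sentinel values (e.g. GLCM
Correlation -> 1) rather than raising.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .datatypes import DiscretizedROI

# one offset per +/- pair covering the 26-neighbourhood at Chebyshev distance 1
DIRECTIONS_13 = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)

_EPS = np.finfo(np.float64).tiny

GLCM_FEATURE_NAMES = (
    "Autocorrelation",
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
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)

GLRLM_FEATURE_NAMES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)

GLSZM_FEATURE_NAMES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
)

GLDM_FEATURE_NAMES = (
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

NGTDM_FEATURE_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")


def _shifted(arr: np.ndarray, offset: tuple[int, int, int], fill=0) -> np.ndarray:
    """arr sampled at +offset: out[v] = arr[v + offset], padded with fill."""
    out = np.full_like(arr, fill)
    src, dst = [], []
    for n, o in zip(arr.shape, offset):
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(droi: DiscretizedROI, offset: tuple[int, int, int]) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix for one direction offset.

    Returns an all-zero matrix if the direction has no co-occurring in-mask
    pair.
    """
    ng = droi.n_levels
    lvl, mask = droi.levels, droi.mask
    nb_lvl = _shifted(lvl, offset)
    nb_mask = _shifted(mask.astype(np.uint8), offset).astype(bool)
    valid = mask & nb_mask
    P = np.zeros((ng, ng), dtype=np.float64)
    if valid.any():
        np.add.at(P, (lvl[valid] - 1, nb_lvl[valid] - 1), 1.0)
        P = P + P.T
        P /= P.sum()
    return P


def _glcm_stats(P: np.ndarray) -> dict[str, float]:
    ng = P.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sig_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sig_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([P[ii + jj == k].sum() for k in k_sum])
    k_diff = np.arange(0, ng)
    p_diff = np.array([P[np.abs(ii - jj) == k].sum() for k in k_diff])

    def ent(p):
        nz = p[p > 0]
        return float(-(nz * np.log2(nz)).sum())

    da = float((k_diff * p_diff).sum())
    corr = float(((ii * jj * P).sum() - mu_x * mu_y) / (sig_x * sig_y)) if sig_x > 0 and sig_y > 0 else 1.0

    hxy = ent(P.ravel())
    outer = np.outer(px, py)
    nzP = P > 0
    hxy1 = float(-(P[nzP] * np.log2(outer[nzP] + _EPS)).sum())
    nzo = outer > 0
    hxy2 = float(-(outer[nzo] * np.log2(outer[nzo])).sum())
    hx, hy = ent(px), ent(py)
    imc1 = float((hxy - hxy1) / max(hx, hy)) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    # MCC: second largest eigenvalue of Q
    if ng > 1 and px.min() >= 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = px[:, None] * py[None, :]
            Pn = np.where(denom > 0, P / np.where(denom > 0, denom, 1.0), 0.0)
        Q = Pn @ P.T  # Q[i,j] = sum_k P[i,k]P[j,k]/(px[i] py[k])
        eig = np.sort(np.real(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(0.0, eig[-2]))) if len(eig) > 1 else 1.0
    else:
        mcc = 1.0

    inv_var = float((p_diff[1:] / k_diff[1:] ** 2).sum()) if ng > 1 else 0.0

    return {
        "Autocorrelation": float((ii * jj * P).sum()),
        "ClusterProminence": float(((ii + jj - mu_x - mu_y) ** 4 * P).sum()),
        "ClusterShade": float(((ii + jj - mu_x - mu_y) ** 3 * P).sum()),
        "ClusterTendency": float(((ii + jj - mu_x - mu_y) ** 2 * P).sum()),
        "Contrast": float(((ii - jj) ** 2 * P).sum()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(p_diff),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "Id": float((p_diff / (1.0 + k_diff)).sum()),
        "Idm": float((p_diff / (1.0 + k_diff**2)).sum()),
        "Idmn": float((p_diff / (1.0 + (k_diff / ng) ** 2)).sum()),
        "Idn": float((p_diff / (1.0 + k_diff / ng)).sum()),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": mu_x,
        "JointEnergy": float((P**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(P.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": ent(p_sum),
        "SumSquares": float(((ii - mu_x) ** 2 * P).sum()),
    }


def glcm_features(
    droi: DiscretizedROI,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> dict[str, float]:
    """The 24 co-occurrence statistics, averaged over direction offsets."""
    per_dir = []
    for off in directions:
        P = glcm_matrix(droi, off)
        if P.sum() > 0:
            per_dir.append(_glcm_stats(P))
    if not per_dir:
        raise ValueError("no co-occurring voxel pairs in any direction (degenerate ROI)")
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLCM_FEATURE_NAMES}


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_matrix(droi: DiscretizedROI, offset: tuple[int, int, int]) -> np.ndarray:
    """Run-length matrix P[level-1, runlength-1] for one direction."""
    lvl, mask = droi.levels, droi.mask
    ng = droi.n_levels
    # continuation: next voxel along +offset is in-mask with the same level
    nb_lvl = _shifted(lvl, offset)
    nb_mask = _shifted(mask.astype(np.uint8), offset).astype(bool)
    cont = mask & nb_mask & (lvl == nb_lvl)
    # run start: not a continuation of the previous voxel along -offset
    neg = tuple(-o for o in offset)
    prev_cont = _shifted(cont.astype(np.uint8), neg).astype(bool)
    start = mask & ~prev_cont

    # run length at each start: 1 + longest chain of continuations
    length = np.ones_like(lvl, dtype=np.int64)
    g = cont.copy()
    k = 1
    while g.any():
        length += g
        shift_off = tuple(o * k for o in offset)
        g = g & _shifted(cont.astype(np.uint8), shift_off).astype(bool)
        k += 1

    max_len = int(length[start].max()) if start.any() else 1
    P = np.zeros((ng, max_len), dtype=np.float64)
    np.add.at(P, (lvl[start] - 1, length[start] - 1), 1.0)
    return P


def _rl_style_stats(P: np.ndarray, n_vox: int, names: tuple[str, ...], axis2: str) -> dict[str, float]:
    """Shared statistics of GLRLM/GLSZM-style (level x size) matrices.

    ``axis2`` tags the second axis ('Run' or 'Zone'/'Area') purely to map
    onto the canonical feature names.
    """
    nz = P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=np.float64)
    j = np.arange(1, P.shape[1] + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = P / nz
    mu_i = (ii * p).sum()
    mu_j = (jj * p).sum()
    pg = P.sum(axis=1)  # per gray level
    ps = P.sum(axis=0)  # per run length / zone size
    nzp = p[p > 0]
    if axis2 == "Run":
        return {
            "GrayLevelNonUniformity": float((pg**2).sum() / nz),
            "GrayLevelNonUniformityNormalized": float((pg**2).sum() / nz**2),
            "GrayLevelVariance": float(((ii - mu_i) ** 2 * p).sum()),
            "HighGrayLevelRunEmphasis": float((P * ii**2).sum() / nz),
            "LongRunEmphasis": float((P * jj**2).sum() / nz),
            "LongRunHighGrayLevelEmphasis": float((P * ii**2 * jj**2).sum() / nz),
            "LongRunLowGrayLevelEmphasis": float((P * jj**2 / ii**2).sum() / nz),
            "LowGrayLevelRunEmphasis": float((P / ii**2).sum() / nz),
            "RunEntropy": float(-(nzp * np.log2(nzp)).sum()),
            "RunLengthNonUniformity": float((ps**2).sum() / nz),
            "RunLengthNonUniformityNormalized": float((ps**2).sum() / nz**2),
            "RunPercentage": float(nz / n_vox),
            "RunVariance": float(((jj - mu_j) ** 2 * p).sum()),
            "ShortRunEmphasis": float((P / jj**2).sum() / nz),
            "ShortRunHighGrayLevelEmphasis": float((P * ii**2 / jj**2).sum() / nz),
            "ShortRunLowGrayLevelEmphasis": float((P / (ii**2 * jj**2)).sum() / nz),
        }
    return {
        "GrayLevelNonUniformity": float((pg**2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum() / nz**2),
        "GrayLevelVariance": float(((ii - mu_i) ** 2 * p).sum()),
        "HighGrayLevelZoneEmphasis": float((P * ii**2).sum() / nz),
        "LargeAreaEmphasis": float((P * jj**2).sum() / nz),
        "LargeAreaHighGrayLevelEmphasis": float((P * ii**2 * jj**2).sum() / nz),
        "LargeAreaLowGrayLevelEmphasis": float((P * jj**2 / ii**2).sum() / nz),
        "LowGrayLevelZoneEmphasis": float((P / ii**2).sum() / nz),
        "SizeZoneNonUniformity": float((ps**2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((ps**2).sum() / nz**2),
        "SmallAreaEmphasis": float((P / jj**2).sum() / nz),
        "SmallAreaHighGrayLevelEmphasis": float((P * ii**2 / jj**2).sum() / nz),
        "SmallAreaLowGrayLevelEmphasis": float((P / (ii**2 * jj**2)).sum() / nz),
        "ZoneEntropy": float(-(nzp * np.log2(nzp)).sum()),
        "ZonePercentage": float(nz / n_vox),
        "ZoneVariance": float(((jj - mu_j) ** 2 * p).sum()),
    }


def glrlm_features(
    droi: DiscretizedROI,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> dict[str, float]:
    """The 16 run-length statistics, averaged over direction offsets."""
    n_vox = int(droi.mask.sum())
    if n_vox == 0:
        raise ValueError("empty ROI")
    per_dir = []
    for off in directions:
        P = glrlm_matrix(droi, off)
        if P.sum() > 0:
            per_dir.append(_rl_style_stats(P, n_vox, GLRLM_FEATURE_NAMES, "Run"))
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLRLM_FEATURE_NAMES}


# ---------------------------------------------------------------------------
# GLSZM


def glszm_matrix(droi: DiscretizedROI) -> np.ndarray:
    """Size-zone matrix P[level-1, size-1]; zones are 26-connected."""
    structure = np.ones((3, 3, 3), dtype=bool)
    ng = droi.n_levels
    sizes_per_level: list[tuple[int, np.ndarray]] = []
    max_size = 1
    for g in range(1, ng + 1):
        level_mask = droi.levels == g
        if not level_mask.any():
            continue
        labels, n_zones = ndimage.label(level_mask, structure=structure)
        sizes = np.bincount(labels.ravel())[1:]
        sizes_per_level.append((g, sizes))
        max_size = max(max_size, int(sizes.max()))
    P = np.zeros((ng, max_size), dtype=np.float64)
    for g, sizes in sizes_per_level:
        np.add.at(P, (np.full(len(sizes), g - 1), sizes - 1), 1.0)
    return P


def glszm_features(droi: DiscretizedROI) -> dict[str, float]:
    """The 16 size-zone statistics."""
    n_vox = int(droi.mask.sum())
    if n_vox == 0:
        raise ValueError("empty ROI")
    P = glszm_matrix(droi)
    return _rl_style_stats(P, n_vox, GLSZM_FEATURE_NAMES, "Zone")


# ---------------------------------------------------------------------------
# GLDM

_OFFSETS_26 = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
)


def gldm_matrix(droi: DiscretizedROI, alpha: int = 0) -> np.ndarray:
    """Dependence matrix P[level-1, size-1]; size = 1 + number of
    26-neighbours (in mask) whose level differs by at most ``alpha``."""
    lvl, mask = droi.levels, droi.mask
    ng = droi.n_levels
    dep = np.zeros(lvl.shape, dtype=np.int64)
    for off in _OFFSETS_26:
        nb_lvl = _shifted(lvl, off)
        nb_mask = _shifted(mask.astype(np.uint8), off).astype(bool)
        dep += (mask & nb_mask & (np.abs(lvl - nb_lvl) <= alpha)).astype(np.int64)
    size = dep[mask] + 1  # centre voxel included
    P = np.zeros((ng, int(size.max())), dtype=np.float64)
    np.add.at(P, (lvl[mask] - 1, size - 1), 1.0)
    return P


def gldm_features(droi: DiscretizedROI, alpha: int = 0) -> dict[str, float]:
    """The 14 dependence statistics."""
    n_vox = int(droi.mask.sum())
    if n_vox == 0:
        raise ValueError("empty ROI")
    P = gldm_matrix(droi, alpha)
    nz = P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=np.float64)
    j = np.arange(1, P.shape[1] + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = P / nz
    mu_i = (ii * p).sum()
    mu_j = (jj * p).sum()
    pg = P.sum(axis=1)
    pd = P.sum(axis=0)
    nzp = p[p > 0]
    return {
        "DependenceEntropy": float(-(nzp * np.log2(nzp)).sum()),
        "DependenceNonUniformity": float((pd**2).sum() / nz),
        "DependenceNonUniformityNormalized": float((pd**2).sum() / nz**2),
        "DependenceVariance": float(((jj - mu_j) ** 2 * p).sum()),
        "GrayLevelNonUniformity": float((pg**2).sum() / nz),
        "GrayLevelVariance": float(((ii - mu_i) ** 2 * p).sum()),
        "HighGrayLevelEmphasis": float((P * ii**2).sum() / nz),
        "LargeDependenceEmphasis": float((P * jj**2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((P * ii**2 * jj**2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((P * jj**2 / ii**2).sum() / nz),
        "LowGrayLevelEmphasis": float((P / ii**2).sum() / nz),
        "SmallDependenceEmphasis": float((P / jj**2).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((P * ii**2 / jj**2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((P / (ii**2 * jj**2)).sum() / nz),
    }


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_table(droi: DiscretizedROI) -> tuple[np.ndarray, np.ndarray, int]:
    """(n_i, s_i, Nv): per-level voxel counts, summed absolute differences
    from the neighbourhood average, and the number of contributing voxels."""
    lvl, mask = droi.levels, droi.mask
    ng = droi.n_levels
    nb_sum = np.zeros(lvl.shape, dtype=np.float64)
    nb_cnt = np.zeros(lvl.shape, dtype=np.int64)
    for off in _OFFSETS_26:
        nb_lvl = _shifted(lvl, off)
        nb_mask = _shifted(mask.astype(np.uint8), off).astype(bool)
        nb_sum += np.where(nb_mask, nb_lvl, 0)
        nb_cnt += nb_mask.astype(np.int64)
    contrib = mask & (nb_cnt > 0)
    with np.errstate(invalid="ignore"):
        avg = np.where(contrib, nb_sum / np.maximum(nb_cnt, 1), 0.0)
    diff = np.abs(lvl - avg)[contrib]
    lv = lvl[contrib]
    n_i = np.bincount(lv, minlength=ng + 1)[1:].astype(np.float64)
    s_i = np.zeros(ng, dtype=np.float64)
    np.add.at(s_i, lv - 1, diff)
    return n_i, s_i, int(contrib.sum())


def ngtdm_features(droi: DiscretizedROI) -> dict[str, float]:
    """The 5 neighbourhood gray-tone difference statistics."""
    if not droi.mask.any():
        raise ValueError("empty ROI")
    n_i, s_i, nv = ngtdm_table(droi)
    if nv == 0:
        raise ValueError("no voxel has an in-mask neighbour (degenerate ROI)")
    p_i = n_i / nv
    i = np.arange(1, len(n_i) + 1, dtype=np.float64)
    present = p_i > 0
    ngp = int(present.sum())

    ps = float((p_i * s_i).sum())
    coarseness = float(1.0 / ps) if ps > 0 else 1e6

    ip, pp, sp = i[present], p_i[present], s_i[present]
    di = ip[:, None] - ip[None, :]

    if ngp > 1:
        contrast = float(
            (pp[:, None] * pp[None, :] * di**2).sum()
            / (ngp * (ngp - 1))
            * (s_i.sum() / nv)
        )
        busy_den = float(np.abs(ip * pp - (ip * pp)[:, None]).sum())
        busyness = float(ps / busy_den) if busy_den > 0 else 0.0
        complexity = float(
            (np.abs(di) * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
             / (pp[:, None] + pp[None, :])).sum() / nv
        )
        s_sum = float(s_i.sum())
        strength = float(((pp[:, None] + pp[None, :]) * di**2).sum() / s_sum) if s_sum > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
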
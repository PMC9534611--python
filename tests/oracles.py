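"""Independent brute-force reference implementations used only by the tests.

Everything here is written as plain loops straight from the defining
formulas, deliberately sharing no code with the package, so agreement is a
genuine two-route check.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# gray-level matrices by exhaustive enumeration


def glcm_matrix_bf(levels: np.ndarray, mask: np.ndarray, ng: int, offset) -> np.ndarray:
    P = np.zeros((ng, ng))
    nz, ny, nx = levels.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                for sign in (1, -1):
                    zz, yy, xx = z + sign * offset[0], y + sign * offset[1], x + sign * offset[2]
                    if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx and mask[zz, yy, xx]:
                        P[levels[z, y, x] - 1, levels[zz, yy, xx] - 1] += 1
    s = P.sum()
    return P / s if s > 0 else P


def glcm_stats_bf(P: np.ndarray) -> dict[str, float]:
    ng = P.shape[0]
    px = [sum(P[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(P[i, j] for i in range(ng)) for j in range(ng)]
    mux = sum((i + 1) * px[i] for i in range(ng))
    muy = sum((j + 1) * py[j] for j in range(ng))
    sigx = math.sqrt(sum((i + 1 - mux) ** 2 * px[i] for i in range(ng)))
    sigy = math.sqrt(sum((j + 1 - muy) ** 2 * py[j] for j in range(ng)))

    psum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    pdiff = {k: 0.0 for k in range(ng)}
    for i in range(ng):
        for j in range(ng):
            psum[i + j + 2] += P[i, j]
            pdiff[abs(i - j)] += P[i, j]

    def ent(vals):
        return -sum(v * math.log2(v) for v in vals if v > 0)

    out = {}
    out["Autocorrelation"] = sum(
        (i + 1) * (j + 1) * P[i, j] for i in range(ng) for j in range(ng)
    )
    for name, power in (("ClusterTendency", 2), ("ClusterShade", 3), ("ClusterProminence", 4)):
        out[name] = sum(
            (i + 1 + j + 1 - mux - muy) ** power * P[i, j]
            for i in range(ng)
            for j in range(ng)
        )
    out["Contrast"] = sum((i - j) ** 2 * P[i, j] for i in range(ng) for j in range(ng))
    if sigx > 0 and sigy > 0:
        out["Correlation"] = (
            sum((i + 1) * (j + 1) * P[i, j] for i in range(ng) for j in range(ng))
            - mux * muy
        ) / (sigx * sigy)
    else:
        out["Correlation"] = 1.0
    da = sum(k * pdiff[k] for k in pdiff)
    out["DifferenceAverage"] = da
    out["DifferenceEntropy"] = ent(pdiff.values())
    out["DifferenceVariance"] = sum((k - da) ** 2 * pdiff[k] for k in pdiff)
    out["Id"] = sum(pdiff[k] / (1 + k) for k in pdiff)
    out["Idm"] = sum(pdiff[k] / (1 + k * k) for k in pdiff)
    out["Idmn"] = sum(pdiff[k] / (1 + (k / ng) ** 2) for k in pdiff)
    out["Idn"] = sum(pdiff[k] / (1 + k / ng) for k in pdiff)
    hxy = ent(P.ravel())
    hxy1 = -sum(
        P[i, j] * math.log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if P[i, j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if px[i] * py[j] > 0
    )
    hx, hy = ent(px), ent(py)
    out["Imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    out["Imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    out["InverseVariance"] = sum(pdiff[k] / k**2 for k in pdiff if k >= 1)
    out["JointAverage"] = mux
    out["JointEnergy"] = sum(P[i, j] ** 2 for i in range(ng) for j in range(ng))
    out["JointEntropy"] = hxy
    if ng > 1:
        Q = np.zeros((ng, ng))
        for i in range(ng):
            for j in range(ng):
                Q[i, j] = sum(
                    P[i, k] * P[j, k] / (px[i] * py[k])
                    for k in range(ng)
                    if px[i] * py[k] > 0
                )
        eig = sorted(np.real(np.linalg.eigvals(Q)))
        out["MCC"] = math.sqrt(max(0.0, eig[-2]))
    else:
        out["MCC"] = 1.0
    out["MaximumProbability"] = P.max()
    out["SumAverage"] = sum(k * psum[k] for k in psum)
    out["SumEntropy"] = ent(psum.values())
    out["SumSquares"] = sum(
        (i + 1 - mux) ** 2 * P[i, j] for i in range(ng) for j in range(ng)
    )
    return {k: float(v) for k, v in out.items()}


def glrlm_matrix_bf(levels: np.ndarray, mask: np.ndarray, ng: int, offset) -> np.ndarray:
    runs: list[tuple[int, int]] = []
    nz, ny, nx = levels.shape

    def inside(p):
        return all(0 <= c < n for c, n in zip(p, (nz, ny, nx))) and mask[p]

    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                p = (z, y, x)
                if not mask[p]:
                    continue
                prev = (z - offset[0], y - offset[1], x - offset[2])
                if inside(prev) and levels[prev] == levels[p]:
                    continue  # not a run start
                length = 1
                cur = p
                while True:
                    nxt = tuple(c + o for c, o in zip(cur, offset))
                    if inside(nxt) and levels[nxt] == levels[p]:
                        length += 1
                        cur = nxt
                    else:
                        break
                runs.append((levels[p], length))
    max_len = max(l for _, l in runs)
    P = np.zeros((ng, max_len))
    for g, l in runs:
        P[g - 1, l - 1] += 1
    return P


def glszm_matrix_bf(levels: np.ndarray, mask: np.ndarray, ng: int) -> np.ndarray:
    nz, ny, nx = levels.shape
    seen = np.zeros_like(mask, dtype=bool)
    zones: list[tuple[int, int]] = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x] or seen[z, y, x]:
                    continue
                g = levels[z, y, x]
                stack, size = [(z, y, x)], 0
                seen[z, y, x] = True
                while stack:
                    cz, cy, cx = stack.pop()
                    size += 1
                    for dz in (-1, 0, 1):
                        for dy in (-1, 0, 1):
                            for dx in (-1, 0, 1):
                                q = (cz + dz, cy + dy, cx + dx)
                                if (
                                    0 <= q[0] < nz and 0 <= q[1] < ny and 0 <= q[2] < nx
                                    and mask[q] and not seen[q] and levels[q] == g
                                ):
                                    seen[q] = True
                                    stack.append(q)
                zones.append((g, size))
    max_size = max(s for _, s in zones)
    P = np.zeros((ng, max_size))
    for g, s in zones:
        P[g - 1, s - 1] += 1
    return P


def gldm_matrix_bf(levels: np.ndarray, mask: np.ndarray, ng: int, alpha: int = 0) -> np.ndarray:
    nz, ny, nx = levels.shape
    deps: list[tuple[int, int]] = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                count = 0
                for dz in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            if (dz, dy, dx) == (0, 0, 0):
                                continue
                            q = (z + dz, y + dy, x + dx)
                            if (
                                0 <= q[0] < nz and 0 <= q[1] < ny and 0 <= q[2] < nx
                                and mask[q]
                                and abs(int(levels[q]) - int(levels[z, y, x])) <= alpha
                            ):
                                count += 1
                deps.append((levels[z, y, x], count + 1))
    max_d = max(d for _, d in deps)
    P = np.zeros((ng, max_d))
    for g, d in deps:
        P[g - 1, d - 1] += 1
    return P


def ngtdm_table_bf(levels: np.ndarray, mask: np.ndarray, ng: int):
    nz, ny, nx = levels.shape
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    nv = 0
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                nb = []
                for dz in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            if (dz, dy, dx) == (0, 0, 0):
                                continue
                            q = (z + dz, y + dy, x + dx)
                            if 0 <= q[0] < nz and 0 <= q[1] < ny and 0 <= q[2] < nx and mask[q]:
                                nb.append(int(levels[q]))
                if not nb:
                    continue
                g = int(levels[z, y, x])
                n_i[g - 1] += 1
                s_i[g - 1] += abs(g - sum(nb) / len(nb))
                nv += 1
    return n_i, s_i, nv


# ---------------------------------------------------------------------------
# discrete wavelet transform by direct convolve-and-downsample


def dwt1d_bf(x: np.ndarray, filt: np.ndarray, mode: str = "symmetric") -> np.ndarray:
    """Single-level 1D analysis filter: boundary-extend, convolve, keep every
    second sample (offset 1)."""
    x = np.asarray(x, float)
    f = np.asarray(filt, float)
    L = len(f)
    if mode == "symmetric":
        left = x[: L - 1][::-1]
        right = x[-(L - 1):][::-1]
        ext = np.concatenate([left, x, right])
        full = np.convolve(ext, f, mode="valid")
        return full[1::2]
    raise ValueError(f"unsupported mode {mode!r}")


def dwt2_bf(M: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """(cA, cH, cV, cD) by separable filtering: columns (axis 0) then rows."""

    def along(axis_mat, f, axis):
        return np.apply_along_axis(dwt1d_bf, axis, axis_mat, f)

    low0 = along(M, lo, 0)
    high0 = along(M, hi, 0)
    cA = along(low0, lo, 1)
    cV = along(low0, hi, 1)
    cH = along(high0, lo, 1)
    cD = along(high0, hi, 1)
    return cA, cH, cV, cD


# ---------------------------------------------------------------------------
# misc closed forms


def ols_slope_se_bf(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    xb, yb = x.mean(), y.mean()
    sxx = ((x - xb) ** 2).sum()
    slope = ((x - xb) * (y - yb)).sum() / sxx
    resid = y - (yb + slope * (x - xb))
    se = math.sqrt((resid**2).sum() / (n - 2) / sxx)
    return slope, se


def icc2_bf(m: np.ndarray) -> float:
    """ICC(2,1) from the explicit two-way ANOVA table."""
    m = np.asarray(m, float)
    n, k = m.shape
    grand = m.mean()
    msr = k * ((m.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((m.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((m - grand) ** 2).sum() - k * ((m.mean(axis=1) - grand) ** 2).sum() \
        - n * ((m.mean(axis=0) - grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def auc_mann_whitney(scores: np.ndarray, y: np.ndarray) -> float:
    pos = scores[y == 1]
    neg = scores[y != 1]
    wins = 0.0
    for a in pos:
        for b in neg:
            wins += 1.0 if a > b else (0.5 if a == b else 0.0)
    return wins / (len(pos) * len(neg))


def paired_permutation_auc_test(
    s1: np.ndarray, s2: np.ndarray, y: np.ndarray, n_perm: int, seed: int
) -> float:
    """Two-sided paired permutation test on the AUC difference: under H0 the
    two models' scores are exchangeable within each subject."""
    rng = np.random.default_rng(seed)
    s1, s2 = np.asarray(s1, float), np.asarray(s2, float)
    obs = abs(auc_mann_whitney(s1, y) - auc_mann_whitney(s2, y))
    hits = 0
    for _ in range(n_perm):
        flip = rng.random(len(y)) < 0.5
        a = np.where(flip, s2, s1)
        b = np.where(flip, s1, s2)
        if abs(auc_mann_whitney(a, y) - auc_mann_whitney(b, y)) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def rl_stats_bf(P: np.ndarray, n_vox: int, kind: str) -> dict[str, float]:
    """GLRLM ('Run') / GLSZM ('Zone') statistics by explicit summation."""
    ng, nl = P.shape
    nz = P.sum()
    mu_i = sum((i + 1) * P[i, j] / nz for i in range(ng) for j in range(nl))
    mu_j = sum((j + 1) * P[i, j] / nz for i in range(ng) for j in range(nl))
    pg = [sum(P[i, j] for j in range(nl)) for i in range(ng)]
    ps = [sum(P[i, j] for i in range(ng)) for j in range(nl)]
    ent = -sum(
        (P[i, j] / nz) * math.log2(P[i, j] / nz)
        for i in range(ng)
        for j in range(nl)
        if P[i, j] > 0
    )

    def emp(fi, fj):
        return sum(
            P[i, j] * fi(i + 1) * fj(j + 1) for i in range(ng) for j in range(nl)
        ) / nz

    one = lambda _: 1.0
    sq = lambda v: float(v * v)
    inv_sq = lambda v: 1.0 / (v * v)
    base = {
        "GrayLevelNonUniformity": sum(g * g for g in pg) / nz,
        "GrayLevelNonUniformityNormalized": sum(g * g for g in pg) / nz**2,
        "GrayLevelVariance": sum(
            (i + 1 - mu_i) ** 2 * P[i, j] / nz for i in range(ng) for j in range(nl)
        ),
    }
    if kind == "Run":
        base.update(
            {
                "HighGrayLevelRunEmphasis": emp(sq, one),
                "LongRunEmphasis": emp(one, sq),
                "LongRunHighGrayLevelEmphasis": emp(sq, sq),
                "LongRunLowGrayLevelEmphasis": emp(inv_sq, sq),
                "LowGrayLevelRunEmphasis": emp(inv_sq, one),
                "RunEntropy": ent,
                "RunLengthNonUniformity": sum(s * s for s in ps) / nz,
                "RunLengthNonUniformityNormalized": sum(s * s for s in ps) / nz**2,
                "RunPercentage": nz / n_vox,
                "RunVariance": sum(
                    (j + 1 - mu_j) ** 2 * P[i, j] / nz for i in range(ng) for j in range(nl)
                ),
                "ShortRunEmphasis": emp(one, inv_sq),
                "ShortRunHighGrayLevelEmphasis": emp(sq, inv_sq),
                "ShortRunLowGrayLevelEmphasis": emp(inv_sq, inv_sq),
            }
        )
    else:
        base.update(
            {
                "HighGrayLevelZoneEmphasis": emp(sq, one),
                "LargeAreaEmphasis": emp(one, sq),
                "LargeAreaHighGrayLevelEmphasis": emp(sq, sq),
                "LargeAreaLowGrayLevelEmphasis": emp(inv_sq, sq),
                "LowGrayLevelZoneEmphasis": emp(inv_sq, one),
                "SizeZoneNonUniformity": sum(s * s for s in ps) / nz,
                "SizeZoneNonUniformityNormalized": sum(s * s for s in ps) / nz**2,
                "SmallAreaEmphasis": emp(one, inv_sq),
                "SmallAreaHighGrayLevelEmphasis": emp(sq, inv_sq),
                "SmallAreaLowGrayLevelEmphasis": emp(inv_sq, inv_sq),
                "ZoneEntropy": ent,
                "ZonePercentage": nz / n_vox,
                "ZoneVariance": sum(
                    (j + 1 - mu_j) ** 2 * P[i, j] / nz for i in range(ng) for j in range(nl)
                ),
            }
        )
    return {k: float(v) for k, v in base.items()}


def gldm_stats_bf(P: np.ndarray) -> dict[str, float]:
    ng, nd = P.shape
    nz = P.sum()
    mu_i = sum((i + 1) * P[i, j] / nz for i in range(ng) for j in range(nd))
    mu_j = sum((j + 1) * P[i, j] / nz for i in range(ng) for j in range(nd))
    pg = [sum(P[i, j] for j in range(nd)) for i in range(ng)]
    pd_ = [sum(P[i, j] for i in range(ng)) for j in range(nd)]

    def emp(fi, fj):
        return sum(
            P[i, j] * fi(i + 1) * fj(j + 1) for i in range(ng) for j in range(nd)
        ) / nz

    one = lambda _: 1.0
    sq = lambda v: float(v * v)
    inv_sq = lambda v: 1.0 / (v * v)
    return {
        "DependenceEntropy": -sum(
            (P[i, j] / nz) * math.log2(P[i, j] / nz)
            for i in range(ng)
            for j in range(nd)
            if P[i, j] > 0
        ),
        "DependenceNonUniformity": sum(d * d for d in pd_) / nz,
        "DependenceNonUniformityNormalized": sum(d * d for d in pd_) / nz**2,
        "DependenceVariance": sum(
            (j + 1 - mu_j) ** 2 * P[i, j] / nz for i in range(ng) for j in range(nd)
        ),
        "GrayLevelNonUniformity": sum(g * g for g in pg) / nz,
        "GrayLevelVariance": sum(
            (i + 1 - mu_i) ** 2 * P[i, j] / nz for i in range(ng) for j in range(nd)
        ),
        "HighGrayLevelEmphasis": emp(sq, one),
        "LargeDependenceEmphasis": emp(one, sq),
        "LargeDependenceHighGrayLevelEmphasis": emp(sq, sq),
        "LargeDependenceLowGrayLevelEmphasis": emp(inv_sq, sq),
        "LowGrayLevelEmphasis": emp(inv_sq, one),
        "SmallDependenceEmphasis": emp(one, inv_sq),
        "SmallDependenceHighGrayLevelEmphasis": emp(sq, inv_sq),
        "SmallDependenceLowGrayLevelEmphasis": emp(inv_sq, inv_sq),
    }


def ngtdm_stats_bf(n_i: np.ndarray, s_i: np.ndarray, nv: int) -> dict[str, float]:
    ng = len(n_i)
    p_i = n_i / nv
    idx = [i for i in range(ng) if p_i[i] > 0]
    ngp = len(idx)
    ps = sum(p_i[i] * s_i[i] for i in idx)
    coarseness = 1.0 / ps if ps > 0 else 1e6
    if ngp > 1:
        contrast = (
            sum(
                p_i[i] * p_i[j] * (i - j) ** 2
                for i in idx
                for j in idx
            )
            / (ngp * (ngp - 1))
            * (sum(s_i) / nv)
        )
        busy_den = sum(
            abs((i + 1) * p_i[i] - (j + 1) * p_i[j]) for i in idx for j in idx
        )
        busyness = ps / busy_den if busy_den > 0 else 0.0
        complexity = sum(
            abs(i - j) * (p_i[i] * s_i[i] + p_i[j] * s_i[j]) / (p_i[i] + p_i[j])
            for i in idx
            for j in idx
        ) / nv
        s_sum = sum(s_i)
        strength = (
            sum((p_i[i] + p_i[j]) * (i - j) ** 2 for i in idx for j in idx) / s_sum
            if s_sum > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Busyness": float(busyness),
        "Coarseness": float(coarseness),
        "Complexity": float(complexity),
        "Contrast": float(contrast),
        "Strength": float(strength),
    }
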
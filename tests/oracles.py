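"""Independent brute-force oracles for the texture and first-order features.

Everything here is written as plain Python loops straight from the
matrix/feature definitions, deliberately sharing no code path with the
vectorized package implementation it cross-checks.
"""

from __future__ import annotations

import math

import numpy as np

EPS = np.spacing(1.0)

DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))


# ---------------------------------------------------------------------------
# GLCM


def naive_glcm(levels, mask, n_levels, offset):
    """Symmetric co-occurrence counts by explicit pixel loops."""
    h, w = levels.shape
    dy, dx = offset
    p = np.zeros((n_levels, n_levels))
    for y in range(h):
        for x in range(w):
            y2, x2 = y + dy, x + dx
            if 0 <= y2 < h and 0 <= x2 < w and mask[y, x] and mask[y2, x2]:
                i, j = levels[y, x] - 1, levels[y2, x2] - 1
                p[i, j] += 1
                p[j, i] += 1
    return p


def naive_glcm_features(counts):
    ng = counts.shape[0]
    total = counts.sum()
    if total == 0:
        counts = np.eye(1)
        total = 1.0
        ng = 1
    p = counts / total
    i_idx = list(range(1, ng + 1))
    px = [sum(p[i - 1][j - 1] for j in i_idx) for i in i_idx]
    py = [sum(p[i - 1][j - 1] for i in i_idx) for j in i_idx]
    ux = sum(i * px[i - 1] for i in i_idx)
    uy = sum(j * py[j - 1] for j in i_idx)
    sx = math.sqrt(sum((i - ux) ** 2 * px[i - 1] for i in i_idx))
    sy = math.sqrt(sum((j - uy) ** 2 * py[j - 1] for j in i_idx))

    psum = {}
    pdiff = {}
    for i in i_idx:
        for j in i_idx:
            psum[i + j] = psum.get(i + j, 0.0) + p[i - 1][j - 1]
            pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + p[i - 1][j - 1]

    hx = -sum(v * math.log2(v + EPS) for v in px)
    hy = -sum(v * math.log2(v + EPS) for v in py)
    hxy = -sum(
        p[i - 1][j - 1] * math.log2(p[i - 1][j - 1] + EPS)
        for i in i_idx
        for j in i_idx
    )
    hxy1 = -sum(
        p[i - 1][j - 1] * math.log2(px[i - 1] * py[j - 1] + EPS)
        for i in i_idx
        for j in i_idx
    )
    hxy2 = -sum(
        px[i - 1] * py[j - 1] * math.log2(px[i - 1] * py[j - 1] + EPS)
        for i in i_idx
        for j in i_idx
    )
    da = sum(k * v for k, v in pdiff.items())

    out = {}
    out["Autocorrelation"] = sum(
        i * j * p[i - 1][j - 1] for i in i_idx for j in i_idx
    )
    out["JointAverage"] = ux
    for name, power in (
        ("ClusterProminence", 4),
        ("ClusterShade", 3),
        ("ClusterTendency", 2),
    ):
        out[name] = sum(
            (i + j - ux - uy) ** power * p[i - 1][j - 1]
            for i in i_idx
            for j in i_idx
        )
    out["Contrast"] = sum(
        (i - j) ** 2 * p[i - 1][j - 1] for i in i_idx for j in i_idx
    )
    if sx * sy == 0:
        out["Correlation"] = 1.0
    else:
        num = sum(i * j * p[i - 1][j - 1] for i in i_idx for j in i_idx) - ux * uy
        out["Correlation"] = num / (sx * sy)
    out["DifferenceAverage"] = da
    out["DifferenceEntropy"] = -sum(
        v * math.log2(v + EPS) for v in pdiff.values()
    )
    out["DifferenceVariance"] = sum(
        (k - da) ** 2 * v for k, v in pdiff.items()
    )
    out["JointEnergy"] = sum(
        p[i - 1][j - 1] ** 2 for i in i_idx for j in i_idx
    )
    out["JointEntropy"] = hxy
    out["Imc1"] = 0.0 if max(hx, hy) == 0 else (hxy - hxy1) / max(hx, hy)
    out["Imc2"] = math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy))))
    out["Idm"] = sum(v / (1 + k**2) for k, v in pdiff.items())
    out["MCC"] = _naive_mcc(p, px, py, ng)
    out["Idmn"] = sum(v / (1 + (k / ng) ** 2) for k, v in pdiff.items())
    out["Id"] = sum(v / (1 + k) for k, v in pdiff.items())
    out["Idn"] = sum(v / (1 + k / ng) for k, v in pdiff.items())
    out["InverseVariance"] = sum(
        v / k**2 for k, v in pdiff.items() if k >= 1
    )
    out["MaximumProbability"] = max(
        p[i - 1][j - 1] for i in i_idx for j in i_idx
    )
    out["SumAverage"] = sum(k * v for k, v in psum.items())
    out["SumEntropy"] = -sum(v * math.log2(v + EPS) for v in psum.values())
    out["SumSquares"] = sum(
        (i - ux) ** 2 * p[i - 1][j - 1] for i in i_idx for j in i_idx
    )
    return out


def _naive_mcc(p, px, py, ng):
    occupied = [i for i in range(ng) if px[i] > 0]
    if len(occupied) < 2:
        return 1.0
    m = len(occupied)
    q = np.zeros((m, m))
    for a, i in enumerate(occupied):
        for b, j in enumerate(occupied):
            q[a, b] = sum(
                p[i][k] * p[j][k] / (px[i] * py[k])
                for k in occupied
                if py[k] > 0
            )
    ev = sorted(np.real(np.linalg.eigvals(q)))
    return math.sqrt(max(0.0, ev[-2]))


def naive_glcm_features_avg(levels, mask, n_levels, distances):
    per = []
    for d in distances:
        for dy, dx in DIRECTIONS:
            per.append(
                naive_glcm_features(
                    naive_glcm(levels, mask, n_levels, (dy * d, dx * d))
                )
            )
    return {k: float(np.mean([m[k] for m in per])) for k in per[0]}


# ---------------------------------------------------------------------------
# GLRLM


def naive_glrlm(levels, mask, n_levels, direction):
    h, w = levels.shape
    dy, dx = direction
    runs = []
    # starting points: all cells without a predecessor along the direction
    for y in range(h):
        for x in range(w):
            py_, px_ = y - dy, x - dx
            if 0 <= py_ < h and 0 <= px_ < w:
                continue
            line = []
            cy, cx = y, x
            while 0 <= cy < h and 0 <= cx < w:
                line.append(levels[cy, cx] if mask[cy, cx] else 0)
                cy += dy
                cx += dx
            val, length = 0, 0
            for v in line + [0 if line[-1] != 0 else -1]:
                if v == val:
                    length += 1
                else:
                    if val > 0:
                        runs.append((val, length))
                    val, length = v, 1
    max_len = max((l for _, l in runs), default=1)
    r = np.zeros((n_levels, max_len))
    for v, l in runs:
        r[v - 1, l - 1] += 1
    return r


def naive_rlm_features(r, n_pixels, kind):
    """Feature formulas shared by GLRLM ('Run') and GLSZM ('Zone')."""
    ng, nl = r.shape
    nr = r.sum()
    p = r / nr
    out = {}
    short = sum(r[i, j] / (j + 1) ** 2 for i in range(ng) for j in range(nl)) / nr
    long_ = sum(r[i, j] * (j + 1) ** 2 for i in range(ng) for j in range(nl)) / nr
    gln = sum(r[i, :].sum() ** 2 for i in range(ng)) / nr
    lnu = sum(r[:, j].sum() ** 2 for j in range(nl)) / nr
    mu_i = sum((i + 1) * p[i, :].sum() for i in range(ng))
    mu_j = sum((j + 1) * p[:, j].sum() for j in range(nl))
    glv = sum(
        p[i, j] * ((i + 1) - mu_i) ** 2 for i in range(ng) for j in range(nl)
    )
    lv = sum(
        p[i, j] * ((j + 1) - mu_j) ** 2 for i in range(ng) for j in range(nl)
    )
    ent = -sum(
        p[i, j] * math.log2(p[i, j] + EPS) for i in range(ng) for j in range(nl)
    )
    lgl = sum(r[i, :].sum() / (i + 1) ** 2 for i in range(ng)) / nr
    hgl = sum(r[i, :].sum() * (i + 1) ** 2 for i in range(ng)) / nr
    sl = sum(
        r[i, j] / ((i + 1) ** 2 * (j + 1) ** 2)
        for i in range(ng)
        for j in range(nl)
    ) / nr
    sh = sum(
        r[i, j] * (i + 1) ** 2 / (j + 1) ** 2
        for i in range(ng)
        for j in range(nl)
    ) / nr
    ll = sum(
        r[i, j] * (j + 1) ** 2 / (i + 1) ** 2
        for i in range(ng)
        for j in range(nl)
    ) / nr
    lh = sum(
        r[i, j] * (i + 1) ** 2 * (j + 1) ** 2
        for i in range(ng)
        for j in range(nl)
    ) / nr
    if kind == "Run":
        names = [
            "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
            "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
            "RunLengthNonUniformityNormalized", "RunPercentage",
            "GrayLevelVariance", "RunVariance", "RunEntropy",
            "LowGrayLevelRunEmphasis", "HighGrayLevelRunEmphasis",
            "ShortRunLowGrayLevelEmphasis", "ShortRunHighGrayLevelEmphasis",
            "LongRunLowGrayLevelEmphasis", "LongRunHighGrayLevelEmphasis",
        ]
    else:
        names = [
            "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
            "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
            "SizeZoneNonUniformityNormalized", "ZonePercentage",
            "GrayLevelVariance", "ZoneVariance", "ZoneEntropy",
            "LowGrayLevelZoneEmphasis", "HighGrayLevelZoneEmphasis",
            "SmallAreaLowGrayLevelEmphasis", "SmallAreaHighGrayLevelEmphasis",
            "LargeAreaLowGrayLevelEmphasis", "LargeAreaHighGrayLevelEmphasis",
        ]
    vals = [
        short, long_, gln, gln / nr, lnu, lnu / nr, nr / n_pixels,
        glv, lv, ent, lgl, hgl, sl, sh, ll, lh,
    ]
    return dict(zip(names, vals))


def naive_glrlm_features(levels, mask, n_levels):
    per = []
    n_pixels = int(mask.sum())
    for direction in DIRECTIONS:
        r = naive_glrlm(levels, mask, n_levels, direction)
        per.append(naive_rlm_features(r, n_pixels, "Run"))
    return {k: float(np.mean([d[k] for d in per])) for k in per[0]}


# ---------------------------------------------------------------------------
# GLSZM (zones by breadth-first flood fill)


def naive_glszm(levels, mask, n_levels):
    h, w = levels.shape
    seen = np.zeros((h, w), dtype=bool)
    zones = []
    for y in range(h):
        for x in range(w):
            if not mask[y, x] or seen[y, x]:
                continue
            g = levels[y, x]
            stack = [(y, x)]
            seen[y, x] = True
            size = 0
            while stack:
                cy, cx = stack.pop()
                size += 1
                for ddy in (-1, 0, 1):
                    for ddx in (-1, 0, 1):
                        ny, nx = cy + ddy, cx + ddx
                        if (
                            0 <= ny < h
                            and 0 <= nx < w
                            and mask[ny, nx]
                            and not seen[ny, nx]
                            and levels[ny, nx] == g
                        ):
                            seen[ny, nx] = True
                            stack.append((ny, nx))
            zones.append((g, size))
    max_size = max((s for _, s in zones), default=1)
    m = np.zeros((n_levels, max_size))
    for g, s in zones:
        m[g - 1, s - 1] += 1
    return m


def naive_glszm_features(levels, mask, n_levels):
    m = naive_glszm(levels, mask, n_levels)
    return naive_rlm_features(m, int(mask.sum()), "Zone")


# ---------------------------------------------------------------------------
# NGTDM


def naive_ngtdm_features(levels, mask, n_levels):
    h, w = levels.shape
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            nb = []
            for ddy in (-1, 0, 1):
                for ddx in (-1, 0, 1):
                    if ddy == 0 and ddx == 0:
                        continue
                    ny, nx = y + ddy, x + ddx
                    if 0 <= ny < h and 0 <= nx < w and mask[ny, nx]:
                        nb.append(levels[ny, nx])
            if not nb:
                continue
            g = levels[y, x]
            n_i[g - 1] += 1
            s_i[g - 1] += abs(g - sum(nb) / len(nb))
    n = n_i.sum()
    p_i = n_i / n
    occ = [i for i in range(n_levels) if p_i[i] > 0]
    ngp = len(occ)
    den = sum(p_i[i] * s_i[i] for i in occ)
    coarseness = 1.0 / den if den > 0 else 1e6
    if ngp > 1:
        contrast = (
            sum(
                p_i[i] * p_i[j] * ((i + 1) - (j + 1)) ** 2
                for i in occ
                for j in occ
            )
            / (ngp * (ngp - 1))
        ) * (sum(s_i) / n)
        busy_den = sum(
            abs((i + 1) * p_i[i] - (j + 1) * p_i[j]) for i in occ for j in occ
        )
        busyness = den / busy_den if busy_den > 0 else 0.0
        complexity = (
            sum(
                abs((i + 1) - (j + 1))
                * (p_i[i] * s_i[i] + p_i[j] * s_i[j])
                / (p_i[i] + p_i[j])
                for i in occ
                for j in occ
            )
            / n
        )
        s_tot = sum(s_i)
        strength = (
            sum(
                (p_i[i] + p_i[j]) * ((i + 1) - (j + 1)) ** 2
                for i in occ
                for j in occ
            )
            / s_tot
            if s_tot > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# GLDM


def naive_gldm_features(levels, mask, n_levels, alpha=0):
    h, w = levels.shape
    entries = []
    max_dep = 0
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            dep = 0
            for ddy in (-1, 0, 1):
                for ddx in (-1, 0, 1):
                    if ddy == 0 and ddx == 0:
                        continue
                    ny, nx = y + ddy, x + ddx
                    if (
                        0 <= ny < h
                        and 0 <= nx < w
                        and mask[ny, nx]
                        and abs(levels[y, x] - levels[ny, nx]) <= alpha
                    ):
                        dep += 1
            entries.append((levels[y, x], dep))
            max_dep = max(max_dep, dep)
    p = np.zeros((n_levels, max_dep + 1))
    for g, d in entries:
        p[g - 1, d] += 1
    nz = p.sum()
    ng, nd = p.shape
    pn = p / nz
    mu_i = sum((i + 1) * pn[i, :].sum() for i in range(ng))
    mu_j = sum((j + 1) * pn[:, j].sum() for j in range(nd))
    return {
        "SmallDependenceEmphasis": sum(
            p[i, j] / (j + 1) ** 2 for i in range(ng) for j in range(nd)
        )
        / nz,
        "LargeDependenceEmphasis": sum(
            p[i, j] * (j + 1) ** 2 for i in range(ng) for j in range(nd)
        )
        / nz,
        "GrayLevelNonUniformity": sum(p[i, :].sum() ** 2 for i in range(ng)) / nz,
        "DependenceNonUniformity": sum(p[:, j].sum() ** 2 for j in range(nd)) / nz,
        "DependenceNonUniformityNormalized": sum(
            p[:, j].sum() ** 2 for j in range(nd)
        )
        / nz**2,
        "GrayLevelVariance": sum(
            pn[i, j] * ((i + 1) - mu_i) ** 2 for i in range(ng) for j in range(nd)
        ),
        "DependenceVariance": sum(
            pn[i, j] * ((j + 1) - mu_j) ** 2 for i in range(ng) for j in range(nd)
        ),
        "DependenceEntropy": -sum(
            pn[i, j] * math.log2(pn[i, j] + EPS)
            for i in range(ng)
            for j in range(nd)
        ),
        "LowGrayLevelEmphasis": sum(
            p[i, :].sum() / (i + 1) ** 2 for i in range(ng)
        )
        / nz,
        "HighGrayLevelEmphasis": sum(
            p[i, :].sum() * (i + 1) ** 2 for i in range(ng)
        )
        / nz,
        "SmallDependenceLowGrayLevelEmphasis": sum(
            p[i, j] / ((i + 1) ** 2 * (j + 1) ** 2)
            for i in range(ng)
            for j in range(nd)
        )
        / nz,
        "SmallDependenceHighGrayLevelEmphasis": sum(
            p[i, j] * (i + 1) ** 2 / (j + 1) ** 2
            for i in range(ng)
            for j in range(nd)
        )
        / nz,
        "LargeDependenceLowGrayLevelEmphasis": sum(
            p[i, j] * (j + 1) ** 2 / (i + 1) ** 2
            for i in range(ng)
            for j in range(nd)
        )
        / nz,
        "LargeDependenceHighGrayLevelEmphasis": sum(
            p[i, j] * (i + 1) ** 2 * (j + 1) ** 2
            for i in range(ng)
            for j in range(nd)
        )
        / nz,
    }


# ---------------------------------------------------------------------------
# first-order


def naive_firstorder(values, bin_width, pixel_area):
    x = sorted(float(v) for v in values)
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    sd = math.sqrt(var)

    def pct(q):
        return float(np.percentile(np.asarray(x), q))

    lo = x[0]
    counts = {}
    for v in x:
        b = int(math.floor((v - lo) / bin_width))
        counts[b] = counts.get(b, 0) + 1
    probs = [c / n for c in counts.values()]
    mid = [v for v in x if pct(10) <= v <= pct(90)]
    mid_mean = sum(mid) / len(mid) if mid else 0.0
    return {
        "Energy": sum(v**2 for v in x),
        "TotalEnergy": sum(v**2 for v in x) * pixel_area,
        "Entropy": -sum(p * math.log2(p) for p in probs),
        "Minimum": x[0],
        "10Percentile": pct(10),
        "90Percentile": pct(90),
        "Maximum": x[-1],
        "Mean": mean,
        "Median": pct(50),
        "InterquartileRange": pct(75) - pct(25),
        "Range": x[-1] - x[0],
        "MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "RobustMeanAbsoluteDeviation": (
            sum(abs(v - mid_mean) for v in mid) / len(mid) if mid else 0.0
        ),
        "RootMeanSquared": math.sqrt(sum(v**2 for v in x) / n),
        "Skewness": 0.0
        if sd == 0
        else (sum((v - mean) ** 3 for v in x) / n) / sd**3,
        "Kurtosis": 3.0
        if var == 0
        else (sum((v - mean) ** 4 for v in x) / n) / var**2,
        "Variance": var,
        "Uniformity": sum(p**2 for p in probs),
    }
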
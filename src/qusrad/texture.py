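"""Gray-level texture matrices and their features on 2-D masked images.

Implements the five standard IBSI texture families on discretized
(integer-level) images restricted to a boolean mask:

* GLCM  - co-occurrence, 4 directions x configurable distances, symmetric,
          features averaged over all direction-distance matrices (24)
* GLRLM - run lengths, 4 directions, features averaged over directions (16)
* GLSZM - 8-connected size zones, single matrix (16)
* NGTDM - neighborhood gray-tone differences, distance-1 kernel (5)
* GLDM  - dependence matrix, distance 1, dependence tolerance 0 (14)

Degenerate regions (a single gray level) take the conventional values
(e.g. GLCM correlation = 1) so that constant patches produce defined,
stable features.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "glcm_matrix",
    "glcm_features",
    "glrlm_matrix",
    "glrlm_features",
    "glszm_matrix",
    "glszm_features",
    "ngtdm_table",
    "ngtdm_features",
    "gldm_matrix",
    "gldm_features",
    "texture_features",
    "TEXTURE_FEATURE_NAMES",
]

_EPS = np.spacing(1.0)

# 2-D directions (dy, dx); the opposite directions are implied by symmetry
_DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))


def _check(levels: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    if levels.shape != mask.shape or levels.ndim != 2:
        raise ValueError("levels and mask must be 2-D arrays of equal shape")
    if not mask.any():
        raise ValueError("mask is empty")
    return levels.astype(np.int64), mask


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(
    levels: np.ndarray, mask: np.ndarray, n_levels: int, offset: tuple[int, int]
) -> np.ndarray:
    """Symmetric co-occurrence count matrix for one (dy, dx) offset."""
    levels, mask = _check(levels, mask)
    dy, dx = offset
    h, w = levels.shape
    ys = slice(max(0, -dy), min(h, h - dy))
    xs = slice(max(0, -dx), min(w, w - dx))
    ys2 = slice(max(0, dy), min(h, h + dy))
    xs2 = slice(max(0, dx), min(w, w + dx))
    a = levels[ys, xs]
    b = levels[ys2, xs2]
    valid = mask[ys, xs] & mask[ys2, xs2]
    p = np.zeros((n_levels, n_levels))
    np.add.at(p, (a[valid] - 1, b[valid] - 1), 1)
    return p + p.T


def _glcm_single(p: np.ndarray) -> dict[str, float]:
    total = p.sum()
    if total == 0:
        # no valid pairs for this offset; treat as the degenerate case
        p = np.eye(1)
        total = 1.0
    p = p / total
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float(i @ px)
    uy = float(i @ py)
    sx = float(np.sqrt(((i - ux) ** 2) @ px))
    sy = float(np.sqrt(((i - uy) ** 2) @ py))
    ii, jj = np.meshgrid(i, i, indexing="ij")

    # diagonal / cross-diagonal distributions
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.bincount(
        (ii + jj).ravel(), weights=p.ravel(), minlength=2 * ng + 1
    )[2:]
    k_diff = np.arange(0, ng)
    p_diff = np.bincount(
        np.abs(ii - jj).ravel(), weights=p.ravel(), minlength=ng
    )[:ng]

    hx = -float(np.sum(px * np.log2(px + _EPS)))
    hy = -float(np.sum(py * np.log2(py + _EPS)))
    hxy = -float(np.sum(p * np.log2(p + _EPS)))
    pxpy = np.outer(px, py)
    hxy1 = -float(np.sum(p * np.log2(pxpy + _EPS)))
    hxy2 = -float(np.sum(pxpy * np.log2(pxpy + _EPS)))

    da = float(np.sum(p_diff * k_diff))
    corr_num = float(np.sum(p * ii * jj)) - ux * uy
    out = {
        "Autocorrelation": float(np.sum(p * ii * jj)),
        "JointAverage": ux,
        "ClusterProminence": float(np.sum(p * (ii + jj - ux - uy) ** 4)),
        "ClusterShade": float(np.sum(p * (ii + jj - ux - uy) ** 3)),
        "ClusterTendency": float(np.sum(p * (ii + jj - ux - uy) ** 2)),
        "Contrast": float(np.sum(p * (ii - jj) ** 2)),
        "Correlation": 1.0 if sx * sy == 0 else corr_num / (sx * sy),
        "DifferenceAverage": da,
        "DifferenceEntropy": -float(np.sum(p_diff * np.log2(p_diff + _EPS))),
        "DifferenceVariance": float(np.sum(p_diff * (k_diff - da) ** 2)),
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": hxy,
        "Imc1": 0.0 if max(hx, hy) == 0 else (hxy - hxy1) / max(hx, hy),
        "Imc2": float(np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - hxy))))),
        "Idm": float(np.sum(p_diff / (1 + k_diff**2))),
        "MCC": _glcm_mcc(p, px, py),
        "Idmn": float(np.sum(p_diff / (1 + (k_diff / ng) ** 2))),
        "Id": float(np.sum(p_diff / (1 + k_diff))),
        "Idn": float(np.sum(p_diff / (1 + k_diff / ng))),
        "InverseVariance": float(np.sum(p_diff[1:] / k_diff[1:] ** 2)),
        "MaximumProbability": float(p.max()),
        "SumAverage": float(np.sum(p_sum * k_sum)),
        "SumEntropy": -float(np.sum(p_sum * np.log2(p_sum + _EPS))),
        "SumSquares": float(np.sum(p * (ii - ux) ** 2)),
    }
    return out


def _glcm_mcc(p: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    """Maximal correlation coefficient: sqrt of the second-largest
    eigenvalue of Q(i, j) = sum_k p(i,k) p(j,k) / (px(i) py(k))."""
    occ = px > 0
    if occ.sum() < 2:
        return 1.0
    ps = p[np.ix_(occ, occ)]
    pxs = px[occ]
    pys = py[occ]
    q = (ps / pxs[:, None]) @ (ps / pys[None, :]).T
    ev = np.sort(np.real(np.linalg.eigvals(q)))
    return float(np.sqrt(max(0.0, ev[-2])))


def glcm_features(
    levels: np.ndarray,
    mask: np.ndarray,
    n_levels: int,
    distances: tuple[int, ...] = (1,),
) -> dict[str, float]:
    """GLCM features averaged over all direction-by-distance matrices."""
    per_matrix = []
    for d in distances:
        for dy, dx in _DIRECTIONS:
            p = glcm_matrix(levels, mask, n_levels, (dy * d, dx * d))
            per_matrix.append(_glcm_single(p))
    return {k: float(np.mean([m[k] for m in per_matrix])) for k in per_matrix[0]}


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_matrix(
    levels: np.ndarray, mask: np.ndarray, n_levels: int, direction: tuple[int, int]
) -> np.ndarray:
    """Run-length count matrix R[level, run_length] for one direction.

    Out-of-mask pixels break runs.
    """
    levels, mask = _check(levels, mask)
    vals = np.where(mask, levels, 0)
    lines = _lines_along(vals, direction)
    max_len = max(len(l) for l in lines)
    r = np.zeros((n_levels, max_len))
    vs, ls = [], []
    for line in lines:
        line = np.asarray(line)
        # run-length encode: boundaries where the value changes
        edges = np.r_[0, np.flatnonzero(line[1:] != line[:-1]) + 1, len(line)]
        run_vals = line[edges[:-1]]
        run_lens = np.diff(edges)
        keep = run_vals > 0
        vs.append(run_vals[keep])
        ls.append(run_lens[keep])
    v = np.concatenate(vs)
    l = np.concatenate(ls)
    np.add.at(r, (v - 1, l - 1), 1)
    return r


def _lines_along(arr: np.ndarray, direction: tuple[int, int]) -> list[np.ndarray]:
    dy, dx = direction
    if (dy, dx) == (0, 1):
        return list(arr)
    if (dy, dx) == (1, 0):
        return list(arr.T)
    if (dy, dx) == (1, 1):
        return [np.diagonal(arr, k) for k in range(-arr.shape[0] + 1, arr.shape[1])]
    if (dy, dx) == (1, -1):
        fl = np.fliplr(arr)
        return [np.diagonal(fl, k) for k in range(-fl.shape[0] + 1, fl.shape[1])]
    raise ValueError(f"unsupported direction {direction}")


def _rlm_style_features(
    r: np.ndarray, n_pixels: int, prefix: str
) -> dict[str, float]:
    """Shared run-length/size-zone feature formulas.

    ``prefix`` switches the naming between the GLRLM and GLSZM variants.
    """
    nr = r.sum()
    if nr == 0:
        r = np.zeros((1, 1))
        r[0, 0] = 1
        nr = 1.0
    i = np.arange(1, r.shape[0] + 1, dtype=float)
    j = np.arange(1, r.shape[1] + 1, dtype=float)
    p = r / nr
    pg = r.sum(axis=1)  # per gray level
    pl = r.sum(axis=0)  # per run length / zone size
    mu_i = float(np.sum(p.sum(axis=1) * i))
    mu_j = float(np.sum(p.sum(axis=0) * j))
    run = prefix == "Run"
    names = {
        "short": "ShortRunEmphasis" if run else "SmallAreaEmphasis",
        "long": "LongRunEmphasis" if run else "LargeAreaEmphasis",
        "gln": "GrayLevelNonUniformity",
        "glnn": "GrayLevelNonUniformityNormalized",
        "lnu": "RunLengthNonUniformity" if run else "SizeZoneNonUniformity",
        "lnun": "RunLengthNonUniformityNormalized"
        if run
        else "SizeZoneNonUniformityNormalized",
        "pct": "RunPercentage" if run else "ZonePercentage",
        "glv": "GrayLevelVariance",
        "lv": "RunVariance" if run else "ZoneVariance",
        "ent": "RunEntropy" if run else "ZoneEntropy",
        "lgl": "LowGrayLevelRunEmphasis" if run else "LowGrayLevelZoneEmphasis",
        "hgl": "HighGrayLevelRunEmphasis" if run else "HighGrayLevelZoneEmphasis",
        "sl": "ShortRunLowGrayLevelEmphasis" if run else "SmallAreaLowGrayLevelEmphasis",
        "sh": "ShortRunHighGrayLevelEmphasis"
        if run
        else "SmallAreaHighGrayLevelEmphasis",
        "ll": "LongRunLowGrayLevelEmphasis" if run else "LargeAreaLowGrayLevelEmphasis",
        "lh": "LongRunHighGrayLevelEmphasis"
        if run
        else "LargeAreaHighGrayLevelEmphasis",
    }
    return {
        names["short"]: float(np.sum(pl / j**2) / nr),
        names["long"]: float(np.sum(pl * j**2) / nr),
        names["gln"]: float(np.sum(pg**2) / nr),
        names["glnn"]: float(np.sum(pg**2) / nr**2),
        names["lnu"]: float(np.sum(pl**2) / nr),
        names["lnun"]: float(np.sum(pl**2) / nr**2),
        names["pct"]: float(nr / n_pixels),
        names["glv"]: float(np.sum(p * ((i[:, None] - mu_i) ** 2))),
        names["lv"]: float(np.sum(p * ((j[None, :] - mu_j) ** 2))),
        names["ent"]: -float(np.sum(p * np.log2(p + _EPS))),
        names["lgl"]: float(np.sum(pg / i**2) / nr),
        names["hgl"]: float(np.sum(pg * i**2) / nr),
        names["sl"]: float(np.sum(r / (i[:, None] ** 2 * j[None, :] ** 2)) / nr),
        names["sh"]: float(np.sum(r * i[:, None] ** 2 / j[None, :] ** 2) / nr),
        names["ll"]: float(np.sum(r * j[None, :] ** 2 / i[:, None] ** 2) / nr),
        names["lh"]: float(np.sum(r * i[:, None] ** 2 * j[None, :] ** 2) / nr),
    }


def glrlm_features(
    levels: np.ndarray, mask: np.ndarray, n_levels: int
) -> dict[str, float]:
    """GLRLM features averaged over the four 2-D directions."""
    _, m = _check(levels, mask)
    n_pixels = int(m.sum())
    per_dir = []
    for direction in _DIRECTIONS:
        r = glrlm_matrix(levels, mask, n_levels, direction)
        per_dir.append(_rlm_style_features(r, n_pixels, "Run"))
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLSZM


def glszm_matrix(
    levels: np.ndarray, mask: np.ndarray, n_levels: int
) -> np.ndarray:
    """Zone-size count matrix S[level, size] with 8-connected zones."""
    levels, mask = _check(levels, mask)
    structure = np.ones((3, 3), dtype=int)
    per_level: dict[int, np.ndarray] = {}
    max_size = 1
    for g in range(1, n_levels + 1):
        binary = mask & (levels == g)
        if not binary.any():
            continue
        lab, n_zones = ndimage.label(binary, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        per_level[g] = np.bincount(sizes)  # index = zone size
        max_size = max(max_size, int(sizes.max()))
    s_mat = np.zeros((n_levels, max_size))
    for g, counts in per_level.items():
        s_mat[g - 1, : len(counts) - 1] = counts[1:]
    return s_mat


def glszm_features(
    levels: np.ndarray, mask: np.ndarray, n_levels: int
) -> dict[str, float]:
    _, m = _check(levels, mask)
    s = glszm_matrix(levels, mask, n_levels)
    return _rlm_style_features(s, int(m.sum()), "Zone")


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_table(
    levels: np.ndarray, mask: np.ndarray, n_levels: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-level counts n_i and summed absolute differences s_i.

    For every in-mask pixel with at least one in-mask neighbor in its
    distance-1 (8-connected) neighborhood, the absolute difference
    between the pixel's level and the mean level of those neighbors is
    accumulated into its level's s_i.
    """
    levels, mask = _check(levels, mask)
    vals = np.where(mask, levels, 0).astype(float)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0
    nsum = ndimage.correlate(vals, kernel, mode="constant", cval=0.0)
    ncount = ndimage.correlate(mask.astype(float), kernel, mode="constant", cval=0.0)
    use = mask & (ncount > 0)
    diffs = np.abs(levels - nsum / np.where(ncount == 0, 1, ncount))
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    np.add.at(n_i, levels[use] - 1, 1)
    np.add.at(s_i, levels[use] - 1, diffs[use])
    return n_i, s_i


def ngtdm_features(
    levels: np.ndarray, mask: np.ndarray, n_levels: int
) -> dict[str, float]:
    n_i, s_i = ngtdm_table(levels, mask, n_levels)
    n = n_i.sum()
    if n == 0:
        raise ValueError("no pixels with valid neighborhoods")
    p_i = n_i / n
    i = np.arange(1, n_levels + 1, dtype=float)
    occ = p_i > 0
    ngp = int(occ.sum())
    ps, iv, sv = p_i[occ], i[occ], s_i[occ]

    coarseness = float(1.0 / np.sum(ps * sv)) if np.sum(ps * sv) > 0 else 1e6
    if ngp > 1:
        pij = np.abs(iv[:, None] - iv[None, :])
        contrast = (
            float(np.sum(np.outer(ps, ps) * pij**2)) / (ngp * (ngp - 1))
        ) * float(np.sum(sv) / n)
        ipi = iv * ps
        busy_den = float(np.sum(np.abs(ipi[:, None] - ipi[None, :])))
        busyness = float(np.sum(ps * sv)) / busy_den if busy_den > 0 else 0.0
        num = (
            np.abs(iv[:, None] - iv[None, :])
            * (ps[:, None] * sv[:, None] + ps[None, :] * sv[None, :])
            / (ps[:, None] + ps[None, :])
        )
        complexity = float(np.sum(num)) / n
        strength_num = float(
            np.sum((ps[:, None] + ps[None, :]) * (iv[:, None] - iv[None, :]) ** 2)
        )
        strength = strength_num / float(np.sum(sv)) if np.sum(sv) > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# GLDM


def gldm_matrix(
    levels: np.ndarray,
    mask: np.ndarray,
    n_levels: int,
    alpha: int = 0,
) -> np.ndarray:
    """Dependence count matrix P[level, dependence].

    The dependence of a pixel is the number of distance-1 (8-connected)
    in-mask neighbors whose level differs by at most ``alpha``; matrix
    column ``j`` corresponds to dependence ``j - 1``.
    """
    levels, mask = _check(levels, mask)
    h, w = levels.shape
    dep = np.zeros((h, w), dtype=int)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            ys = slice(max(0, -dy), min(h, h - dy))
            xs = slice(max(0, -dx), min(w, w - dx))
            ys2 = slice(max(0, dy), min(h, h + dy))
            xs2 = slice(max(0, dx), min(w, w + dx))
            ok = (
                mask[ys, xs]
                & mask[ys2, xs2]
                & (np.abs(levels[ys, xs] - levels[ys2, xs2]) <= alpha)
            )
            dep[ys, xs] += ok
    max_dep = int(dep[mask].max())
    p = np.zeros((n_levels, max_dep + 1))
    np.add.at(p, (levels[mask] - 1, dep[mask]), 1)
    return p


def gldm_features(
    levels: np.ndarray, mask: np.ndarray, n_levels: int, alpha: int = 0
) -> dict[str, float]:
    p = gldm_matrix(levels, mask, n_levels, alpha)
    nz = p.sum()
    i = np.arange(1, p.shape[0] + 1, dtype=float)
    j = np.arange(1, p.shape[1] + 1, dtype=float)  # dependence j-1, 1-based index
    pn = p / nz
    pg = p.sum(axis=1)
    pd = p.sum(axis=0)
    mu_i = float(np.sum(pn.sum(axis=1) * i))
    mu_j = float(np.sum(pn.sum(axis=0) * j))
    return {
        "SmallDependenceEmphasis": float(np.sum(pd / j**2) / nz),
        "LargeDependenceEmphasis": float(np.sum(pd * j**2) / nz),
        "GrayLevelNonUniformity": float(np.sum(pg**2) / nz),
        "DependenceNonUniformity": float(np.sum(pd**2) / nz),
        "DependenceNonUniformityNormalized": float(np.sum(pd**2) / nz**2),
        "GrayLevelVariance": float(np.sum(pn * (i[:, None] - mu_i) ** 2)),
        "DependenceVariance": float(np.sum(pn * (j[None, :] - mu_j) ** 2)),
        "DependenceEntropy": -float(np.sum(pn * np.log2(pn + _EPS))),
        "LowGrayLevelEmphasis": float(np.sum(pg / i**2) / nz),
        "HighGrayLevelEmphasis": float(np.sum(pg * i**2) / nz),
        "SmallDependenceLowGrayLevelEmphasis": float(
            np.sum(p / (i[:, None] ** 2 * j[None, :] ** 2)) / nz
        ),
        "SmallDependenceHighGrayLevelEmphasis": float(
            np.sum(p * i[:, None] ** 2 / j[None, :] ** 2) / nz
        ),
        "LargeDependenceLowGrayLevelEmphasis": float(
            np.sum(p * j[None, :] ** 2 / i[:, None] ** 2) / nz
        ),
        "LargeDependenceHighGrayLevelEmphasis": float(
            np.sum(p * i[:, None] ** 2 * j[None, :] ** 2) / nz
        ),
    }


# ---------------------------------------------------------------------------
# dispatcher

_FAMILY_FUNCS = {
    "glcm": lambda lv, m, ng, cfg: glcm_features(lv, m, ng, cfg),
    "glrlm": lambda lv, m, ng, cfg: glrlm_features(lv, m, ng),
    "glszm": lambda lv, m, ng, cfg: glszm_features(lv, m, ng),
    "ngtdm": lambda lv, m, ng, cfg: ngtdm_features(lv, m, ng),
    "gldm": lambda lv, m, ng, cfg: gldm_features(lv, m, ng),
}

TEXTURE_FEATURE_NAMES: dict[str, tuple[str, ...]] = {}


def _init_names() -> None:
    img = np.array([[1, 2], [2, 1]])
    msk = np.ones((2, 2), dtype=bool)
    for fam, fn in _FAMILY_FUNCS.items():
        TEXTURE_FEATURE_NAMES[fam] = tuple(sorted(fn(img, msk, 2, (1,))))


_init_names()


def texture_features(
    levels: np.ndarray,
    mask: np.ndarray,
    n_levels: int,
    family: str,
    glcm_distances: tuple[int, ...] = (1, 2, 3, 4, 5),
) -> dict[str, float]:
    """Compute one texture family's features on a discretized image."""
    if family not in _FAMILY_FUNCS:
        raise ValueError(f"unknown texture family {family!r}")
    return _FAMILY_FUNCS[family](levels, mask, n_levels, glcm_distances)
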
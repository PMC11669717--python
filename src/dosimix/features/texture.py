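"""Texture feature families on discretized gray levels.

All matrices are built in 3-D over the 13 unique voxel directions (GLCM,
GLRLM) or the 26-connected neighborhood (GLSZM zones, GLDM dependencies,
NGTDM neighborhood differences).  Inputs are integer level volumes from
:func:`dosimix.features._discretize.discretize` — levels 1..Ng inside the
ROI, 0 outside.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
from scipy import ndimage

_EPS = np.finfo(float).eps

# 13 unique direction offsets (half of the 26-neighborhood)
OFFSETS_13: List[Tuple[int, int, int]] = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

GLCM_NAMES = [
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "Id", "Idm", "Idmn", "Idn",
    "Imc1", "Imc2", "InverseVariance", "JointEnergy", "JointEntropy",
    "MaximumProbability", "SumEntropy", "SumSquares",
]

GLRLM_NAMES = [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]

GLSZM_NAMES = [
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]

GLDM_NAMES = [
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis", "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
]

NGTDM_NAMES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]


def _offset_slices(shape, off):
    sl_a, sl_b = [], []
    for n, o in zip(shape, off):
        if o > 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        elif o < 0:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
        else:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
    return tuple(sl_a), tuple(sl_b)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(levels: np.ndarray, Ng: int, off) -> np.ndarray:
    """Symmetric co-occurrence matrix for one offset, normalized to sum 1."""
    sa, sb = _offset_slices(levels.shape, off)
    gi = levels[sa].ravel()
    gj = levels[sb].ravel()
    ok = (gi > 0) & (gj > 0)
    gi, gj = gi[ok], gj[ok]
    if gi.size == 0:
        return np.zeros((Ng, Ng))
    counts = np.bincount((gi - 1) * Ng + (gj - 1), minlength=Ng * Ng).reshape(Ng, Ng)
    counts = counts + counts.T
    return counts / counts.sum()


def _glcm_features_single(P: np.ndarray) -> Dict[str, float]:
    Ng = P.shape[0]
    i = np.arange(1, Ng + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)  # symmetric: px == py
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())

    k_diff = np.arange(Ng)
    p_diff = np.bincount(np.abs(I - J).ravel(), weights=P.ravel(), minlength=Ng)
    k_sum = np.arange(2, 2 * Ng + 1)
    p_sum = np.bincount((I + J).ravel(), weights=P.ravel(),
                        minlength=2 * Ng + 1)[2:]

    def ent(v):
        nz = v[v > 0]
        return float(-(nz * np.log2(nz)).sum())

    HXY = ent(P.ravel())
    HX = ent(px)
    pxy_prod = np.outer(px, px)
    nz = (P > 0) & (pxy_prod > 0)
    HXY1 = float(-(P[nz] * np.log2(pxy_prod[nz])).sum())
    nz2 = pxy_prod > 0
    HXY2 = float(-(pxy_prod[nz2] * np.log2(pxy_prod[nz2])).sum())

    DA = float((k_diff * p_diff).sum())
    autoc = float((I * J * P).sum())

    out = {
        "Autocorrelation": autoc,
        "JointAverage": mu,
        "ClusterProminence": float((((I + J) - 2 * mu) ** 4 * P).sum()),
        "ClusterShade": float((((I + J) - 2 * mu) ** 3 * P).sum()),
        "ClusterTendency": float((((I + J) - 2 * mu) ** 2 * P).sum()),
        "Contrast": float(((I - J) ** 2 * P).sum()),
        "Correlation": (autoc - mu * mu) / sigma2 if sigma2 > 0 else 1.0,
        "DifferenceAverage": DA,
        "DifferenceEntropy": ent(p_diff),
        "DifferenceVariance": float(((k_diff - DA) ** 2 * p_diff).sum()),
        "Id": float((p_diff / (1.0 + k_diff)).sum()),
        "Idm": float((p_diff / (1.0 + k_diff**2)).sum()),
        "Idmn": float((p_diff / (1.0 + k_diff**2 / Ng**2)).sum()),
        "Idn": float((p_diff / (1.0 + k_diff / Ng)).sum()),
        "Imc1": (HXY - HXY1) / max(HX, _EPS) if HX > 0 else 0.0,
        "Imc2": float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (HXY2 - HXY))))),
        "InverseVariance": float((p_diff[1:] / k_diff[1:] ** 2).sum()),
        "JointEnergy": float((P**2).sum()),
        "JointEntropy": HXY,
        "MaximumProbability": float(P.max()),
        "SumEntropy": ent(p_sum),
        "SumSquares": float(((I - mu) ** 2 * P).sum()),
    }
    return out


def glcm_features(levels: np.ndarray, Ng: int) -> Dict[str, float]:
    """GLCM features averaged over the 13 unique 3-D directions."""
    per_angle = []
    for off in OFFSETS_13:
        P = glcm_matrix(levels, Ng, off)
        if P.sum() > 0:
            per_angle.append(_glcm_features_single(P))
    if not per_angle:
        return dict.fromkeys(GLCM_NAMES, np.nan)
    return {k: float(np.mean([f[k] for f in per_angle])) for k in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def run_length_matrix(levels: np.ndarray, Ng: int, off) -> np.ndarray:
    """Run-length counts P[i-1, r-1] along one direction."""
    shape = levels.shape
    idx = np.indices(shape)
    start = np.zeros(shape, dtype=bool)
    for d in range(3):
        if off[d] > 0:
            start |= idx[d] < off[d]
        elif off[d] < 0:
            start |= idx[d] >= shape[d] + off[d]
    starts = np.argwhere(start)
    Lmax = min(shape[d] for d in range(3) if off[d] != 0)
    n = len(starts)
    V = np.zeros((n, Lmax + 1), dtype=np.int64)  # +1 sentinel column of zeros
    pos = starts.copy()
    for t in range(Lmax):
        inb = np.all((pos >= 0) & (pos < shape), axis=1)
        V[inb, t] = levels[tuple(pos[inb].T)]
        pos = pos + off
    flat = V.ravel()
    change = np.flatnonzero(np.diff(flat) != 0) + 1
    bounds = np.concatenate(([0], change, [flat.size]))
    vals = flat[bounds[:-1]]
    lens = np.diff(bounds)
    keep = vals > 0
    vals, lens = vals[keep], lens[keep]
    P = np.zeros((Ng, Lmax), dtype=float)
    if vals.size:
        np.add.at(P, (vals - 1, np.minimum(lens, Lmax) - 1), 1.0)
    return P


def _sz_style_features(P: np.ndarray, Np: int, names_map: Dict[str, str]) -> Dict[str, float]:
    """Shared emphasis/nonuniformity formulas for GLRLM- and GLSZM-type
    matrices P indexed (gray level i, size/length s)."""
    Ns = P.sum()
    if Ns == 0:
        return {v: np.nan for v in names_map.values()}
    i = np.arange(1, P.shape[0] + 1, dtype=float)
    s = np.arange(1, P.shape[1] + 1, dtype=float)
    Pi = P.sum(axis=1)
    Ps = P.sum(axis=0)
    pnorm = P / Ns
    mu_i = (i * Pi / Ns).sum()
    mu_s = (s * Ps / Ns).sum()
    pz = pnorm[pnorm > 0]
    raw = {
        "small": float(((Ps / s**2).sum()) / Ns),
        "large": float(((Ps * s**2).sum()) / Ns),
        "gln": float((Pi**2).sum() / Ns),
        "glnn": float((Pi**2).sum() / Ns**2),
        "szn": float((Ps**2).sum() / Ns),
        "sznn": float((Ps**2).sum() / Ns**2),
        "pct": float(Ns / Np),
        "glvar": float((((i - mu_i) ** 2) * Pi / Ns).sum()),
        "svar": float((((s - mu_s) ** 2) * Ps / Ns).sum()),
        "ent": float(-(pz * np.log2(pz)).sum()),
        "lgl": float(((Pi / i**2).sum()) / Ns),
        "hgl": float(((Pi * i**2).sum()) / Ns),
        "slgl": float((pnorm / np.outer(i**2, s**2)).sum()),
        "shgl": float((pnorm * np.outer(i**2, 1.0 / s**2)).sum()),
        "llgl": float((pnorm * np.outer(1.0 / i**2, s**2)).sum()),
        "lhgl": float((pnorm * np.outer(i**2, s**2)).sum()),
    }
    return {v: raw[k] for k, v in names_map.items()}


_GLRLM_MAP = {
    "small": "ShortRunEmphasis", "large": "LongRunEmphasis",
    "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
    "szn": "RunLengthNonUniformity", "sznn": "RunLengthNonUniformityNormalized",
    "pct": "RunPercentage", "glvar": "GrayLevelVariance", "svar": "RunVariance",
    "ent": "RunEntropy", "lgl": "LowGrayLevelRunEmphasis",
    "hgl": "HighGrayLevelRunEmphasis", "slgl": "ShortRunLowGrayLevelEmphasis",
    "shgl": "ShortRunHighGrayLevelEmphasis", "llgl": "LongRunLowGrayLevelEmphasis",
    "lhgl": "LongRunHighGrayLevelEmphasis",
}

_GLSZM_MAP = {
    "small": "SmallAreaEmphasis", "large": "LargeAreaEmphasis",
    "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
    "szn": "SizeZoneNonUniformity", "sznn": "SizeZoneNonUniformityNormalized",
    "pct": "ZonePercentage", "glvar": "GrayLevelVariance", "svar": "ZoneVariance",
    "ent": "ZoneEntropy", "lgl": "LowGrayLevelZoneEmphasis",
    "hgl": "HighGrayLevelZoneEmphasis", "slgl": "SmallAreaLowGrayLevelEmphasis",
    "shgl": "SmallAreaHighGrayLevelEmphasis", "llgl": "LargeAreaLowGrayLevelEmphasis",
    "lhgl": "LargeAreaHighGrayLevelEmphasis",
}


def glrlm_features(levels: np.ndarray, Ng: int) -> Dict[str, float]:
    """GLRLM features averaged over the 13 unique 3-D directions."""
    Np = int((levels > 0).sum())
    per_angle = []
    for off in OFFSETS_13:
        P = run_length_matrix(levels, Ng, off)
        if P.sum() > 0:
            per_angle.append(_sz_style_features(P, Np, _GLRLM_MAP))
    if not per_angle:
        return dict.fromkeys(GLRLM_NAMES, np.nan)
    return {k: float(np.mean([f[k] for f in per_angle])) for k in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def size_zone_matrix(levels: np.ndarray, Ng: int) -> np.ndarray:
    """Zone counts P[i-1, s-1]: 26-connected components per gray level."""
    structure = np.ones((3, 3, 3), dtype=int)
    max_size = int((levels > 0).sum())
    if max_size == 0:
        return np.zeros((max(Ng, 1), 1))
    P = np.zeros((Ng, max_size), dtype=float)
    for g in range(1, Ng + 1):
        binary = levels == g
        if not binary.any():
            continue
        lab, nlab = ndimage.label(binary, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        np.add.at(P, (g - 1, sizes - 1), 1.0)
    # trim trailing all-zero size columns for compactness
    nz = np.nonzero(P.sum(axis=0))[0]
    return P[:, : nz[-1] + 1] if nz.size else P[:, :1]


def glszm_features(levels: np.ndarray, Ng: int) -> Dict[str, float]:
    Np = int((levels > 0).sum())
    if Np == 0:
        return dict.fromkeys(GLSZM_NAMES, np.nan)
    P = size_zone_matrix(levels, Ng)
    return _sz_style_features(P, Np, _GLSZM_MAP)


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def dependence_matrix(levels: np.ndarray, Ng: int, alpha: float = 0.0) -> np.ndarray:
    """Dependence counts P[i-1, j-1], j = 1 + number of 26-neighbors inside
    the ROI whose level differs from the center by at most ``alpha``."""
    mask = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for base in OFFSETS_13:
        for off in (base, tuple(-o for o in base)):
            sa, sb = _offset_slices(levels.shape, off)
            both = mask[sa] & mask[sb]
            close = np.abs(levels[sa] - levels[sb]) <= alpha
            dep[sa] += (both & close).astype(np.int64)
    j = dep[mask] + 1
    g = levels[mask]
    Jmax = int(j.max())
    P = np.zeros((Ng, Jmax), dtype=float)
    np.add.at(P, (g - 1, j - 1), 1.0)
    return P


def gldm_features(levels: np.ndarray, Ng: int, alpha: float = 0.0) -> Dict[str, float]:
    Np = int((levels > 0).sum())
    if Np == 0:
        return dict.fromkeys(GLDM_NAMES, np.nan)
    P = dependence_matrix(levels, Ng, alpha)
    Nz = P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=float)
    jj = np.arange(1, P.shape[1] + 1, dtype=float)
    Pi = P.sum(axis=1)
    Pj = P.sum(axis=0)
    pnorm = P / Nz
    mu_i = (i * Pi / Nz).sum()
    mu_j = (jj * Pj / Nz).sum()
    pz = pnorm[pnorm > 0]
    return {
        "SmallDependenceEmphasis": float(((Pj / jj**2).sum()) / Nz),
        "LargeDependenceEmphasis": float(((Pj * jj**2).sum()) / Nz),
        "GrayLevelNonUniformity": float((Pi**2).sum() / Nz),
        "DependenceNonUniformity": float((Pj**2).sum() / Nz),
        "DependenceNonUniformityNormalized": float((Pj**2).sum() / Nz**2),
        "GrayLevelVariance": float((((i - mu_i) ** 2) * Pi / Nz).sum()),
        "DependenceVariance": float((((jj - mu_j) ** 2) * Pj / Nz).sum()),
        "DependenceEntropy": float(-(pz * np.log2(pz)).sum()),
        "LowGrayLevelEmphasis": float(((Pi / i**2).sum()) / Nz),
        "HighGrayLevelEmphasis": float(((Pi * i**2).sum()) / Nz),
        "SmallDependenceLowGrayLevelEmphasis": float(
            (pnorm / np.outer(i**2, jj**2)).sum()
        ),
        "SmallDependenceHighGrayLevelEmphasis": float(
            (pnorm * np.outer(i**2, 1.0 / jj**2)).sum()
        ),
        "LargeDependenceLowGrayLevelEmphasis": float(
            (pnorm * np.outer(1.0 / i**2, jj**2)).sum()
        ),
        "LargeDependenceHighGrayLevelEmphasis": float(
            (pnorm * np.outer(i**2, jj**2)).sum()
        ),
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_components(levels: np.ndarray, Ng: int):
    """Per-level counts n_i and summed absolute differences s_i."""
    mask = levels > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    lev_sum = ndimage.correlate(
        (levels * mask).astype(float), kernel, mode="constant", cval=0.0
    )
    cnt = ndimage.correlate(mask.astype(float), kernel, mode="constant", cval=0.0)
    valid = mask & (cnt > 0)
    A = np.zeros(levels.shape)
    A[valid] = lev_sum[valid] / cnt[valid]
    diff = np.abs(levels - A)
    n_i = np.zeros(Ng)
    s_i = np.zeros(Ng)
    g = levels[valid]
    np.add.at(n_i, g - 1, 1.0)
    np.add.at(s_i, g - 1, diff[valid])
    return n_i, s_i


def ngtdm_features(levels: np.ndarray, Ng: int) -> Dict[str, float]:
    Np = int((levels > 0).sum())
    if Np == 0:
        return dict.fromkeys(NGTDM_NAMES, np.nan)
    n_i, s_i = ngtdm_components(levels, Ng)
    N = n_i.sum()
    if N == 0:
        return dict.fromkeys(NGTDM_NAMES, np.nan)
    p_i = n_i / N
    act = p_i > 0
    i = np.arange(1, Ng + 1, dtype=float)
    Ngp = int(act.sum())

    coars_den = float((p_i * s_i).sum())
    coarseness = 1.0 / coars_den if coars_den > 0 else 1e6

    if Ngp > 1:
        ii, jj = np.meshgrid(i[act], i[act], indexing="ij")
        pi_, pj_ = np.meshgrid(p_i[act], p_i[act], indexing="ij")
        contrast = (
            float((pi_ * pj_ * (ii - jj) ** 2).sum())
            / (Ngp * (Ngp - 1))
            * float(s_i.sum())
            / N
        )
        busy_den = float(np.abs(ii * pi_ - jj * pj_).sum())
        busyness = coars_den / busy_den if busy_den > 0 else 0.0
        si_, sj_ = np.meshgrid(s_i[act], s_i[act], indexing="ij")
        complexity = float(
            (np.abs(ii - jj) * (pi_ * si_ + pj_ * sj_) / (pi_ + pj_)).sum()
        ) / N
        s_sum = float(s_i.sum())
        strength = (
            float(((pi_ + pj_) * (ii - jj) ** 2).sum()) / s_sum if s_sum > 0 else 0.0
        )
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
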
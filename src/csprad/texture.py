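"""Gray-level texture matrices (GLCM, GLRLM, GLSZM, GLDM, NGTDM) and their
features on quantized 3D volumes.

Conventions: distance-1 neighbourhoods over the 13 unique 3D directions
(26-connectivity); GLCM and GLRLM features are computed per direction and
averaged; GLSZM zones and GLDM dependencies use 26-connected neighbourhoods;
GLDM gray-level difference tolerance is 0, and the dependence index is
stored as 1 + the number of dependent neighbours so that small-dependence
formulas stay defined.  All formulas follow the IBSI definitions; gray
levels are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .quantize import QuantizedVolume

_EPS = np.finfo(np.float64).eps

# 13 unique direction vectors: first non-zero component positive.
DIRECTIONS: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(DIRECTIONS) == 13

_STRUCT26 = np.ones((3, 3, 3), dtype=int)


@dataclass
class TextureMatrix:
    """A normalized texture matrix plus its normalization constant.

    For GLCM the matrix is the direction-averaged feature context; ``raw``
    holds per-direction (or single) count matrices and ``norm`` the total
    count (Nr runs, Nz zones/voxels, Np pairs as applicable).
    """

    kind: str
    raw: np.ndarray
    norm: float


def _offset_slices(shape, d):
    """Index slices (src, dst) such that src + d == dst, both in bounds."""
    src, dst = [], []
    for n, step in zip(shape, d):
        if step == 0:
            src.append(slice(None)); dst.append(slice(None))
        elif step > 0:
            src.append(slice(0, n - step)); dst.append(slice(step, n))
        else:
            src.append(slice(-step, n)); dst.append(slice(0, n + step))
    return tuple(src), tuple(dst)


def _shift(arr, d, fill=0):
    """arr shifted so that out[x] = arr[x - d] (zero-filled)."""
    out = np.full_like(arr, fill)
    src, dst = _offset_slices(arr.shape, d)
    out[dst] = arr[src]
    return out


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrices(q: QuantizedVolume) -> list[np.ndarray]:
    """Symmetric co-occurrence count matrices, one per direction."""
    ng = q.n_levels
    labels = q.labels
    inmask = q.mask
    mats = []
    for d in DIRECTIONS:
        src, dst = _offset_slices(labels.shape, d)
        ok = inmask[src] & inmask[dst]
        i = labels[src][ok] - 1
        j = labels[dst][ok] - 1
        m = np.zeros((ng, ng))
        np.add.at(m, (i, j), 1.0)
        mats.append(m + m.T)
    return mats


def _glcm_features_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu_x = float((px * i).sum())          # symmetric: mu_x == mu_y
    sig_x = float(np.sqrt((px * (i - mu_x) ** 2).sum()))

    # diagonal / cross-diagonal distributions
    k_diff = np.arange(ng)                # |i-j| in 0..ng-1
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])

    def ent(v):
        v = v[v > 0]
        return float(-(v * np.log2(v)).sum())

    da = float((p_diff * k_diff).sum())
    feats = {
        "Autocorrelation": float((p * ii * jj).sum()),
        "JointAverage": mu_x,
        "ClusterProminence": float((p * (ii + jj - 2 * mu_x) ** 4).sum()),
        "ClusterShade": float((p * (ii + jj - 2 * mu_x) ** 3).sum()),
        "ClusterTendency": float((p * (ii + jj - 2 * mu_x) ** 2).sum()),
        "Contrast": float((p * (ii - jj) ** 2).sum()),
        "Correlation": 1.0 if sig_x < _EPS else float(
            ((p * (ii - mu_x) * (jj - mu_x)).sum()) / (sig_x * sig_x)),
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(p_diff),
        "DifferenceVariance": float((p_diff * (k_diff - da) ** 2).sum()),
        "JointEnergy": float((p ** 2).sum()),
        "JointEntropy": ent(p),
        "Id": float((p / (1 + np.abs(ii - jj))).sum()),
        "Idm": float((p / (1 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1 + ((ii - jj) / ng) ** 2)).sum()),
        "Idn": float((p / (1 + np.abs(ii - jj) / ng)).sum()),
        "InverseVariance": float(
            (p[ii != jj] / (ii - jj)[ii != jj] ** 2).sum()),
        "MaximumProbability": float(p.max()),
        "SumAverage": float((p_sum * k_sum).sum()),
        "SumEntropy": ent(p_sum),
        "SumSquares": float((p * (ii - mu_x) ** 2).sum()),
    }
    # information measures of correlation
    hxy = feats["JointEntropy"]
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.where(px > 0, np.log2(np.where(px > 0, px, 1)), 0.0)
    hx = float(-(px * lp).sum())
    outer = np.outer(px, px)
    pos = (p > 0) & (outer > 0)
    hxy1 = float(-(p[pos] * np.log2(outer[pos])).sum())
    pos2 = outer > 0
    hxy2 = float(-(outer[pos2] * np.log2(outer[pos2])).sum())
    feats["Imc1"] = 0.0 if hx < _EPS else (hxy - hxy1) / hx
    feats["Imc2"] = float(np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - hxy)))))
    # maximal correlation coefficient
    feats["MCC"] = _mcc(p, px)
    return feats


def _mcc(p: np.ndarray, px: np.ndarray) -> float:
    nz = px > 0
    if nz.sum() < 2:
        return 1.0
    psub = p[np.ix_(nz, nz)]
    pxs = px[nz]
    q = (psub / pxs[:, None]) @ (psub / pxs[None, :]).T
    eig = np.linalg.eigvals(q)
    eig = np.sort(np.abs(eig))[::-1]
    return float(np.sqrt(max(0.0, eig[1].real if len(eig) > 1 else 0.0)))


def glcm_features(q: QuantizedVolume) -> dict[str, float]:
    """Per-direction features averaged over the 13 directions."""
    per_dir = []
    for m in glcm_matrices(q):
        tot = m.sum()
        if tot == 0:
            continue
        per_dir.append(_glcm_features_single(m / tot))
    if not per_dir:
        return {k: float("nan") for k in GLCM_FEATURES}
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_FEATURES}


GLCM_FEATURES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def glrlm_matrices(q: QuantizedVolume) -> list[np.ndarray]:
    """Run-length count matrices P(i, j), one per direction (j = run length)."""
    labels = np.where(q.mask, q.labels, 0)
    ng = q.n_levels
    max_len = max(labels.shape)
    mats = []
    for d in DIRECTIONS:
        same_prev = (labels > 0) & (_shift(labels, d) == labels)
        # c[x] = number of consecutive same-label predecessors along d
        c = np.zeros(labels.shape, dtype=np.int64)
        for _ in range(max_len):
            c_new = np.where(same_prev, _shift(c, d) + 1, 0)
            if np.array_equal(c_new, c):
                break
            c = c_new
        # a run ends where the successor is absent or different
        same_next = (labels > 0) & (_shift(labels, tuple(-x for x in d)) == labels)
        run_end = (labels > 0) & ~same_next
        lengths = c[run_end] + 1
        levels = labels[run_end]
        m = np.zeros((ng, max_len))
        np.add.at(m, (levels - 1, np.minimum(lengths, max_len) - 1), 1.0)
        mats.append(m)
    return mats


def _rl_style_features(m: np.ndarray, np_voxels: int, prefix: str,
                       names: dict[str, str]) -> dict[str, float]:
    """Shared GLRLM/GLSZM/GLDM feature formulas over a (level x size) matrix."""
    nr = m.sum()
    if nr == 0:
        return {v: float("nan") for v in names.values()}
    i = np.arange(1, m.shape[0] + 1, dtype=float)
    j = np.arange(1, m.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = m / nr
    mu_i = float((p * ii).sum())
    mu_j = float((p * jj).sum())
    pe = p[p > 0]
    vals = {
        "SE": float((m / jj ** 2).sum() / nr),
        "LE": float((m * jj ** 2).sum() / nr),
        "GLN": float((m.sum(axis=1) ** 2).sum() / nr),
        "GLNN": float((m.sum(axis=1) ** 2).sum() / nr ** 2),
        "SN": float((m.sum(axis=0) ** 2).sum() / nr),
        "SNN": float((m.sum(axis=0) ** 2).sum() / nr ** 2),
        "PCT": float(nr / np_voxels),
        "GLV": float((p * (ii - mu_i) ** 2).sum()),
        "SV": float((p * (jj - mu_j) ** 2).sum()),
        "ENT": float(-(pe * np.log2(pe)).sum()),
        "LGLE": float((m / ii ** 2).sum() / nr),
        "HGLE": float((m * ii ** 2).sum() / nr),
        "SLGLE": float((m / (ii ** 2 * jj ** 2)).sum() / nr),
        "SHGLE": float((m * ii ** 2 / jj ** 2).sum() / nr),
        "LLGLE": float((m * jj ** 2 / ii ** 2).sum() / nr),
        "LHGLE": float((m * ii ** 2 * jj ** 2).sum() / nr),
    }
    return {full: vals[short] for short, full in names.items()}


_GLRLM_NAMES = {
    "SE": "ShortRunEmphasis", "LE": "LongRunEmphasis",
    "GLN": "GrayLevelNonUniformity", "GLNN": "GrayLevelNonUniformityNormalized",
    "SN": "RunLengthNonUniformity", "SNN": "RunLengthNonUniformityNormalized",
    "PCT": "RunPercentage", "GLV": "GrayLevelVariance", "SV": "RunVariance",
    "ENT": "RunEntropy",
    "LGLE": "LowGrayLevelRunEmphasis", "HGLE": "HighGrayLevelRunEmphasis",
    "SLGLE": "ShortRunLowGrayLevelEmphasis",
    "SHGLE": "ShortRunHighGrayLevelEmphasis",
    "LLGLE": "LongRunLowGrayLevelEmphasis",
    "LHGLE": "LongRunHighGrayLevelEmphasis",
}
GLRLM_FEATURES = tuple(sorted(_GLRLM_NAMES.values()))


def glrlm_features(q: QuantizedVolume) -> dict[str, float]:
    np_voxels = int(q.mask.sum())
    per_dir = [_rl_style_features(m, np_voxels, "glrlm", _GLRLM_NAMES)
               for m in glrlm_matrices(q)]
    return {k: float(np.nanmean([f[k] for f in per_dir]))
            for k in GLRLM_FEATURES}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def glszm_matrix(q: QuantizedVolume) -> TextureMatrix:
    """Zone-size count matrix: 26-connected components of equal gray level."""
    labels = np.where(q.mask, q.labels, 0)
    np_voxels = int(q.mask.sum())
    zone_entries = []
    for g in range(1, q.n_levels + 1):
        comp, n = ndimage.label(labels == g, structure=_STRUCT26)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(comp), comp,
                                   index=np.arange(1, n + 1)).astype(int)
        for s in sizes:
            zone_entries.append((g, s))
    max_size = max((s for _, s in zone_entries), default=1)
    m = np.zeros((q.n_levels, max_size))
    for g, s in zone_entries:
        m[g - 1, s - 1] += 1
    return TextureMatrix(kind="GLSZM", raw=m, norm=float(m.sum()))


_GLSZM_NAMES = {
    "SE": "SmallAreaEmphasis", "LE": "LargeAreaEmphasis",
    "GLN": "GrayLevelNonUniformity", "GLNN": "GrayLevelNonUniformityNormalized",
    "SN": "SizeZoneNonUniformity", "SNN": "SizeZoneNonUniformityNormalized",
    "PCT": "ZonePercentage", "GLV": "GrayLevelVariance", "SV": "ZoneVariance",
    "ENT": "ZoneEntropy",
    "LGLE": "LowGrayLevelZoneEmphasis", "HGLE": "HighGrayLevelZoneEmphasis",
    "SLGLE": "SmallAreaLowGrayLevelEmphasis",
    "SHGLE": "SmallAreaHighGrayLevelEmphasis",
    "LLGLE": "LargeAreaLowGrayLevelEmphasis",
    "LHGLE": "LargeAreaHighGrayLevelEmphasis",
}
GLSZM_FEATURES = tuple(sorted(_GLSZM_NAMES.values()))


def glszm_features(q: QuantizedVolume) -> dict[str, float]:
    m = glszm_matrix(q)
    return _rl_style_features(m.raw, int(q.mask.sum()), "glszm", _GLSZM_NAMES)


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def gldm_matrix(q: QuantizedVolume, alpha: int = 0) -> TextureMatrix:
    """Dependence matrix: j = 1 + count of 26-neighbours with |Δlevel| <= α."""
    labels = np.where(q.mask, q.labels, 0)
    dep = np.zeros(labels.shape, dtype=np.int64)
    for d in DIRECTIONS:
        for dd in (d, tuple(-x for x in d)):
            nb = _shift(labels, dd)
            dep += (q.mask & (nb > 0)
                    & (np.abs(nb - labels) <= alpha)).astype(np.int64)
    levels = labels[q.mask]
    counts = dep[q.mask] + 1
    m = np.zeros((q.n_levels, int(counts.max())))
    np.add.at(m, (levels - 1, counts - 1), 1.0)
    return TextureMatrix(kind="GLDM", raw=m, norm=float(m.sum()))


_GLDM_NAMES = {
    "SE": "SmallDependenceEmphasis", "LE": "LargeDependenceEmphasis",
    "GLN": "GrayLevelNonUniformity", "GLV": "GrayLevelVariance",
    "SN": "DependenceNonUniformity", "SNN": "DependenceNonUniformityNormalized",
    "SV": "DependenceVariance", "ENT": "DependenceEntropy",
    "LGLE": "LowGrayLevelEmphasis", "HGLE": "HighGrayLevelEmphasis",
    "SLGLE": "SmallDependenceLowGrayLevelEmphasis",
    "SHGLE": "SmallDependenceHighGrayLevelEmphasis",
    "LLGLE": "LargeDependenceLowGrayLevelEmphasis",
    "LHGLE": "LargeDependenceHighGrayLevelEmphasis",
}
GLDM_FEATURES = tuple(sorted(_GLDM_NAMES.values()))


def gldm_features(q: QuantizedVolume, alpha: int = 0) -> dict[str, float]:
    m = gldm_matrix(q, alpha=alpha)
    return _rl_style_features(m.raw, int(q.mask.sum()), "gldm", _GLDM_NAMES)


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

NGTDM_FEATURES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")


def ngtdm_table(q: QuantizedVolume):
    """Per-level (n_i, p_i, s_i): counts, probabilities, summed tone
    differences to the mean of valid 26-neighbourhoods."""
    labels = np.where(q.mask, q.labels, 0)
    nb_sum = np.zeros(labels.shape, dtype=np.float64)
    nb_cnt = np.zeros(labels.shape, dtype=np.float64)
    for d in DIRECTIONS:
        for dd in (d, tuple(-x for x in d)):
            nb = _shift(labels, dd)
            valid = nb > 0
            nb_sum += np.where(valid, nb, 0)
            nb_cnt += valid
    has_nb = q.mask & (nb_cnt > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(has_nb, nb_sum / np.maximum(nb_cnt, 1), 0.0)
    ng = q.n_levels
    n = np.zeros(ng)
    s = np.zeros(ng)
    lev = labels[has_nb]
    diff = np.abs(lev - a[has_nb])
    np.add.at(n, lev - 1, 1.0)
    np.add.at(s, lev - 1, diff)
    nvp = n.sum()
    p = n / nvp if nvp > 0 else n
    return n, p, s


def ngtdm_features(q: QuantizedVolume) -> dict[str, float]:
    n, p, s = ngtdm_table(q)
    nvp = n.sum()
    i = np.arange(1, len(n) + 1, dtype=float)
    act = p > 0
    ngp = int(act.sum())
    ps = float((p * s).sum())
    feats = dict.fromkeys(NGTDM_FEATURES, float("nan"))
    if nvp == 0:
        return feats
    feats["Coarseness"] = 1.0 / ps if ps > 0 else 1e6
    if ngp > 1:
        ii, jj = np.meshgrid(i[act], i[act], indexing="ij")
        pi, pj = np.meshgrid(p[act], p[act], indexing="ij")
        si, sj = np.meshgrid(s[act], s[act], indexing="ij")
        feats["Contrast"] = float(
            (pi * pj * (ii - jj) ** 2).sum() / (ngp * (ngp - 1))
            * s.sum() / nvp)
        denom = float(np.abs(i[act] * p[act]
                             - (i[act] * p[act])[:, None]).sum())
        feats["Busyness"] = ps / denom if denom > 0 else 0.0
        feats["Complexity"] = float(
            (np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum() / nvp)
        ssum = s.sum()
        feats["Strength"] = (float(((pi + pj) * (ii - jj) ** 2).sum()) / ssum
                             if ssum > 0 else 0.0)
    else:
        feats["Contrast"] = 0.0
        feats["Busyness"] = 0.0
        feats["Complexity"] = 0.0
        feats["Strength"] = 0.0
    return feats
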
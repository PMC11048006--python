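"""Grey-level texture matrices and their feature batteries.

Five matrix families over the discretised volume, all 3D:

* GLCM  — co-occurrence over the 13 unique unit offsets, symmetrised and
  normalised per offset; each of the 24 features is averaged over offsets.
* GLRLM — run lengths over the same 13 directions, features averaged.
* GLSZM — zone sizes with 26-connected zones (one matrix, no averaging).
* GLDM  — dependence counts at Chebyshev distance 1, tolerance 0.  The
  dependence size of a voxel is 1 + the number of in-mask neighbours with
  an identical level (the +1 counts the voxel itself and keeps the
  small-dependence emphases finite).
* NGTDM — neighbourhood grey-tone differences at Chebyshev distance 1.

Degenerate regions (one grey level, single voxel) return defined limits;
no feature is ever NaN on a non-empty region.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..subregions import EmptyMaskError
from .discretize import DiscretizedVolume

_EPS = np.finfo(np.float64).eps

# 13 unique 3D directions: half of the 26-neighbourhood, first non-zero
# component positive, in fixed lexicographic order.
UNIQUE_OFFSETS: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)
assert len(UNIQUE_OFFSETS) == 13

ALL_OFFSETS: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
)

GLCM_NAMES = (
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
    "MaximumProbability",
    "MCC",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)

GLRLM_NAMES = (
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

GLSZM_NAMES = (
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

GLDM_NAMES = (
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

NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")


def _offset_slices(shape, d):
    """Slice pair (src, dst) such that arr[src] pairs voxel v with arr[dst] at v + d."""
    src, dst = [], []
    for s, di in zip(shape, d):
        if di >= 0:
            src.append(slice(0, s - di))
            dst.append(slice(di, s))
        else:
            src.append(slice(-di, s))
            dst.append(slice(0, s + di))
    return tuple(src), tuple(dst)


def _check_nonempty(disc: DiscretizedVolume) -> None:
    if disc.n_voxels == 0:
        raise EmptyMaskError("texture features require a non-empty region")


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(disc: DiscretizedVolume, offset: tuple[int, int, int]) -> np.ndarray:
    """Symmetrised (unnormalised) co-occurrence counts for one offset."""
    _check_nonempty(disc)
    L = disc.levels
    ng = disc.ng
    src, dst = _offset_slices(L.shape, offset)
    a = L[src].ravel()
    b = L[dst].ravel()
    ok = (a > 0) & (b > 0)
    counts = np.bincount(a[ok] * (ng + 1) + b[ok], minlength=(ng + 1) ** 2)
    m = counts.reshape(ng + 1, ng + 1)[1:, 1:].astype(np.float64)
    return m + m.T


def _glcm_features_single(p: np.ndarray, ng: int) -> dict[str, float]:
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # == py by symmetry
    mu = (px * i).sum()
    sigma2 = (px * (i - mu) ** 2).sum()

    # p_{x+y}(k), k = 2..2Ng and p_{x-y}(k), k = 0..Ng-1
    ksum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.zeros(2 * ng - 1)
    kdiff = np.arange(0, ng, dtype=np.float64)
    p_diff = np.zeros(ng)
    idx_sum = (ii + jj - 2).astype(int)
    idx_diff = np.abs(ii - jj).astype(int)
    np.add.at(p_sum, idx_sum.ravel(), p.ravel())
    np.add.at(p_diff, idx_diff.ravel(), p.ravel())

    nzp = p[p > 0]
    hxy = float(-(nzp * np.log2(nzp)).sum())
    nzx = px[px > 0]
    hx = float(-(nzx * np.log2(nzx)).sum())
    pxpy = np.outer(px, px)
    ok = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[ok] * np.log2(pxpy[ok])).sum())
    okk = pxpy > 0
    hxy2 = float(-(pxpy[okk] * np.log2(pxpy[okk])).sum())

    if sigma2 > 0:
        corr = float(((p * ii * jj).sum() - mu * mu) / sigma2)
    else:
        corr = 1.0  # constant region: perfectly correlated by convention

    da = float((p_diff * kdiff).sum())
    nzd = p_diff[p_diff > 0]
    nzs = p_sum[p_sum > 0]

    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    off_diag = ii != jj
    inv_var = float((p[off_diag] / (ii - jj)[off_diag] ** 2).sum())

    # Maximal correlation coefficient: sqrt of the second-largest eigenvalue
    # of Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k)).
    if ng > 1 and sigma2 > 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = np.outer(px, px)  # px(i) * py(k); symmetric marginals
            w = np.where(denom > 0, p / np.where(denom > 0, denom, 1.0), 0.0)
        q = w @ p.T
        ev = np.linalg.eigvals(q)
        ev = np.sort(np.abs(ev.real))[::-1]
        mcc = float(np.sqrt(max(0.0, ev[1]))) if ev.size > 1 else 1.0
    else:
        mcc = 1.0

    return {
        "Autocorrelation": float((p * ii * jj).sum()),
        "ClusterProminence": float((p * (ii + jj - 2 * mu) ** 4).sum()),
        "ClusterShade": float((p * (ii + jj - 2 * mu) ** 3).sum()),
        "ClusterTendency": float((p * (ii + jj - 2 * mu) ** 2).sum()),
        "Contrast": float((p * (ii - jj) ** 2).sum()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-(nzd * np.log2(nzd)).sum()),
        "DifferenceVariance": float((p_diff * (kdiff - da) ** 2).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": float(mu),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MaximumProbability": float(p.max()),
        "MCC": mcc,
        "SumAverage": float((p_sum * ksum).sum()),
        "SumEntropy": float(-(nzs * np.log2(nzs)).sum()),
        "SumSquares": float(sigma2),
    }


def glcm_features(disc: DiscretizedVolume) -> dict[str, float]:
    """24 co-occurrence features, averaged over the 13 unique offsets."""
    _check_nonempty(disc)
    per_offset = []
    for off in UNIQUE_OFFSETS:
        m = glcm_matrix(disc, off)
        tot = m.sum()
        if tot == 0:
            continue  # no voxel pairs along this offset (e.g. single-voxel region)
        per_offset.append(_glcm_features_single(m / tot, disc.ng))
    if not per_offset:
        # single isolated voxel: fully degenerate co-occurrence
        base = _glcm_features_single(np.array([[1.0]]), 1)
        return {k: base[k] for k in GLCM_NAMES}
    return {k: float(np.mean([f[k] for f in per_offset])) for k in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_matrix(disc: DiscretizedVolume, direction: tuple[int, int, int]) -> np.ndarray:
    """Run-length counts R[level-1, length-1] along one direction."""
    _check_nonempty(disc)
    L = disc.levels
    shape = L.shape
    max_len = int(max(shape))
    d = direction

    # same[v] = voxel v and v+d are both in-mask with identical level
    same = np.zeros(shape, dtype=bool)
    src, dst = _offset_slices(shape, d)
    same[src] = (L[src] > 0) & (L[src] == L[dst])

    # start[v] = in-mask and not continued from v-d
    prev_same = np.zeros(shape, dtype=bool)
    nd = tuple(-c for c in d)
    src_n, dst_n = _offset_slices(shape, nd)
    prev_same[src_n] = (L[src_n] > 0) & (L[src_n] == L[dst_n])
    start = (L > 0) & ~prev_same

    lengths = start.astype(np.int64)
    cur = start & same
    k = 1
    while cur.any():
        lengths[cur] += 1
        # extend: need the link at v + k*d as well
        step = tuple(c * k for c in d)
        shifted = np.zeros(shape, dtype=bool)
        s_src, s_dst = _offset_slices(shape, step)
        shifted[s_src] = same[s_dst]
        k += 1
        cur = cur & shifted

    lv = L[start]
    ln = lengths[start]
    counts = np.bincount((lv - 1) * max_len + (ln - 1), minlength=disc.ng * max_len)
    return counts.reshape(disc.ng, max_len).astype(np.float64)


def _size_matrix_features(m: np.ndarray, n_voxels: int, names, size_name_map) -> dict[str, float]:
    """Shared feature formulas for run-length / zone-size / dependence matrices.

    ``m[i-1, s-1]`` counts entities of grey level i and size s; the 16 (or 14)
    features are the standard weighted-sum emphases over (i, s).
    """
    n = m.sum()
    if n == 0:
        raise EmptyMaskError("empty size matrix")
    nz_cols = np.nonzero(m.sum(axis=0))[0]
    m = m[:, : nz_cols[-1] + 1]  # trailing zero columns carry no weight
    i = np.arange(1, m.shape[0] + 1, dtype=np.float64)
    s = np.arange(1, m.shape[1] + 1, dtype=np.float64)
    ii, ss = np.meshgrid(i, s, indexing="ij")
    p = m / n
    gsum = m.sum(axis=1)  # per grey level
    ssum = m.sum(axis=0)  # per size
    mu_i = (p * ii).sum()
    mu_s = (p * ss).sum()
    nzp = p[p > 0]
    out = {
        "GLN": float((gsum**2).sum() / n),
        "GLNN": float((gsum**2).sum() / n**2),
        "GLV": float((p * (ii - mu_i) ** 2).sum()),
        "HGLE": float((m * ii**2).sum() / n),
        "LGLE": float((m / ii**2).sum() / n),
        "LSE": float((m * ss**2).sum() / n),
        "SSE": float((m / ss**2).sum() / n),
        "LSHGLE": float((m * ss**2 * ii**2).sum() / n),
        "LSLGLE": float((m * ss**2 / ii**2).sum() / n),
        "SSHGLE": float((m * ii**2 / ss**2).sum() / n),
        "SSLGLE": float((m / (ii**2 * ss**2)).sum() / n),
        "SN": float((ssum**2).sum() / n),
        "SNN": float((ssum**2).sum() / n**2),
        "SV": float((p * (ss - mu_s) ** 2).sum()),
        "ENT": float(-(nzp * np.log2(nzp)).sum()),
        "PCT": float(n / n_voxels),
    }
    return {name: out[key] for name, key in zip(names, size_name_map)}


_GLRLM_KEYS = (
    "GLN", "GLNN", "GLV", "HGLE", "LSE", "LSHGLE", "LSLGLE", "LGLE",
    "ENT", "SN", "SNN", "PCT", "SV", "SSE", "SSHGLE", "SSLGLE",
)


def glrlm_features(disc: DiscretizedVolume) -> dict[str, float]:
    """16 run-length features, averaged over the 13 unique directions."""
    _check_nonempty(disc)
    per_dir = [
        _size_matrix_features(
            glrlm_matrix(disc, d), disc.n_voxels, GLRLM_NAMES, _GLRLM_KEYS
        )
        for d in UNIQUE_OFFSETS
    ]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# GLSZM


def glszm_matrix(disc: DiscretizedVolume) -> np.ndarray:
    """Zone-size counts S[level-1, size-1]; zones are 26-connected."""
    _check_nonempty(disc)
    structure = np.ones((3, 3, 3), dtype=bool)
    max_size = disc.n_voxels
    pairs: list[tuple[int, int]] = []
    for g in range(1, disc.ng + 1):
        lab, nlab = ndimage.label(disc.levels == g, structure=structure)
        if nlab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        pairs.extend((g, int(sz)) for sz in sizes)
    m = np.zeros((disc.ng, max_size), dtype=np.float64)
    for g, sz in pairs:
        m[g - 1, sz - 1] += 1
    return m


_GLSZM_KEYS = (
    "GLN", "GLNN", "GLV", "HGLE", "LSE", "LSHGLE", "LSLGLE", "LGLE",
    "SN", "SNN", "SSE", "SSHGLE", "SSLGLE", "ENT", "PCT", "SV",
)


def glszm_features(disc: DiscretizedVolume) -> dict[str, float]:
    """16 zone-size features (26-connected zones)."""
    return _size_matrix_features(
        glszm_matrix(disc), disc.n_voxels, GLSZM_NAMES, _GLSZM_KEYS
    )


# ---------------------------------------------------------------------------
# GLDM


def gldm_matrix(disc: DiscretizedVolume, alpha: int = 0) -> np.ndarray:
    """Dependence counts D[level-1, size-1] at Chebyshev distance 1.

    Size = 1 + number of in-mask neighbours whose level differs by at most
    ``alpha`` from the centre voxel.
    """
    _check_nonempty(disc)
    L = disc.levels
    shape = L.shape
    dep = np.zeros(shape, dtype=np.int64)
    for off in ALL_OFFSETS:
        src, dst = _offset_slices(shape, off)
        hit = (L[src] > 0) & (L[dst] > 0) & (np.abs(L[src] - L[dst]) <= alpha)
        dep[src] += hit
    inmask = L > 0
    size = dep[inmask] + 1  # include the centre voxel
    lv = L[inmask]
    max_size = 27
    counts = np.bincount((lv - 1) * max_size + (size - 1), minlength=disc.ng * max_size)
    return counts.reshape(disc.ng, max_size).astype(np.float64)


_GLDM_KEYS = (
    "ENT", "SN", "SNN", "SV", "GLN", "GLV", "HGLE",
    "LSE", "LSHGLE", "LSLGLE", "LGLE", "SSE", "SSHGLE", "SSLGLE",
)


def gldm_features(disc: DiscretizedVolume, alpha: int = 0) -> dict[str, float]:
    """14 grey-level dependence features (distance 1, tolerance alpha)."""
    return _size_matrix_features(
        gldm_matrix(disc, alpha), disc.n_voxels, GLDM_NAMES, _GLDM_KEYS
    )


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_table(disc: DiscretizedVolume) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-level (count n_i, probability p_i, summed absolute difference s_i).

    s_i sums, over all voxels of level i that have at least one in-mask
    neighbour, |i - mean level of the in-mask neighbours| (26-neighbourhood).
    """
    _check_nonempty(disc)
    L = disc.levels.astype(np.float64)
    inmask = disc.levels > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    nb_sum = ndimage.convolve(L * inmask, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(inmask.astype(np.float64), kernel, mode="constant", cval=0.0)
    has_nb = inmask & (nb_cnt > 0)
    diff = np.zeros_like(L)
    diff[has_nb] = np.abs(L[has_nb] - nb_sum[has_nb] / nb_cnt[has_nb])
    ng = disc.ng
    n = np.bincount(disc.levels[inmask], minlength=ng + 1)[1:].astype(np.float64)
    s = np.zeros(ng)
    np.add.at(s, disc.levels[has_nb] - 1, diff[has_nb])
    p = n / n.sum()
    return n, p, s


def ngtdm_features(disc: DiscretizedVolume) -> dict[str, float]:
    """5 neighbourhood grey-tone difference features."""
    n, p, s = ngtdm_table(disc)
    n_voxels = disc.n_voxels
    i = np.arange(1, disc.ng + 1, dtype=np.float64)
    present = p > 0
    ngp = int(present.sum())
    ip = i[present]
    pp = p[present]
    sp = s[present]

    ps = float((p * s).sum())
    coarseness = 1.0 / ps if ps > 0 else 1e6

    if ngp > 1:
        di = ip[:, None] - ip[None, :]
        pij = pp[:, None] * pp[None, :]
        contrast = float(
            (pij * di**2).sum() / (ngp * (ngp - 1)) * (s.sum() / n_voxels)
        )
        busy_den = float(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum())
        busyness = ps / busy_den if busy_den > 0 else 0.0
        psum = pp[:, None] + pp[None, :]
        complexity = float(
            (np.abs(di) * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :]) / psum).sum()
            / n_voxels
        )
        s_tot = float(s.sum())
        strength = float((psum * di**2).sum() / s_tot) if s_tot > 0 else 0.0
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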
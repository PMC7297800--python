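"""Per-patch radiomics feature kernels.

Everything operates on a cubic neighborhood ("patch") of raw intensities
around a voxel.  First-order statistics are computed on the raw values
(entropy/uniformity/mean gray level on the min-max quantized levels);
second-order GLCM and GLRLM statistics are computed on the quantized patch
over the 13 unique 3D directions at Chebyshev distance 1.

The heavy lifting is in numba-compiled kernels; thin Python wrappers expose
each operation on a single patch for testing and interactive use, and the
fused per-voxel driver in :mod:`periprog.radiomics.table` reuses the same
kernels, so the two paths cannot drift apart.

Conventions (fixed, see docs/methods.md): population variance (divide by
n); skewness m3/sigma^3 and kurtosis m4/sigma^4, both defined as 0 for a
zero-variance patch; logarithms base 2 with 0*log(0) = 0; GLCM correlation
features are 0 when a marginal is degenerate.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .registry import FIRST_ORDER_NAMES, GLCM_NAMES, GLRLM_NAMES

__all__ = [
    "directions_13",
    "quantize",
    "first_order_features",
    "glcm_matrix",
    "glcm_features",
    "glrlm_matrix",
    "glrlm_features",
]

_LN2 = float(np.log(2.0))


def directions_13() -> np.ndarray:
    """The 13 unique 3D offsets at Chebyshev distance 1 (up to sign)."""
    return np.array(
        [
            [1, 0, 0], [0, 1, 0], [0, 0, 1],
            [1, 1, 0], [1, -1, 0], [1, 0, 1], [1, 0, -1],
            [0, 1, 1], [0, 1, -1],
            [1, 1, 1], [1, 1, -1], [1, -1, 1], [1, -1, -1],
        ],
        dtype=np.int64,
    )


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------

@njit(cache=False)
def _quantize_kernel(patch, n_levels):
    """Linear min-max binning into integer levels 1..n_levels."""
    out = np.empty(patch.shape, dtype=np.int64)
    flat = patch.ravel()
    mn = flat[0]
    mx = flat[0]
    for v in flat:
        if v < mn:
            mn = v
        if v > mx:
            mx = v
    oflat = out.ravel()
    if mx == mn or n_levels == 1:
        for i in range(flat.size):
            oflat[i] = 1
    else:
        scale = n_levels / (mx - mn)
        for i in range(flat.size):
            lev = int((flat[i] - mn) * scale) + 1
            if lev > n_levels:
                lev = n_levels
            oflat[i] = lev
    return out


def quantize(patch, n_levels: int = 32) -> np.ndarray:
    """Quantize a patch to integer gray levels 1..n_levels (min-max binning)."""
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    patch = np.ascontiguousarray(patch, dtype=np.float64)
    return _quantize_kernel(patch, n_levels)


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

@njit(cache=False)
def _first_order_kernel(flat, qflat, n_levels, out):
    """13 first-order statistics -> out[0:13] in registry order."""
    n = flat.size
    mean = 0.0
    for v in flat:
        mean += v
    mean /= n
    m2 = 0.0
    m3 = 0.0
    m4 = 0.0
    energy = 0.0
    mn = flat[0]
    mx = flat[0]
    for v in flat:
        d = v - mean
        m2 += d * d
        m3 += d * d * d
        m4 += d * d * d * d
        energy += v * v
        if v < mn:
            mn = v
        if v > mx:
            mx = v
    m2 /= n
    m3 /= n
    m4 /= n
    var = m2
    sd = np.sqrt(var)
    if sd > 0.0:
        skew = m3 / sd**3
        kurt = m4 / (var * var)
    else:
        skew = 0.0
        kurt = 0.0
    rms = np.sqrt(energy / n)
    median = np.median(flat)
    # histogram statistics on the quantized levels
    counts = np.zeros(n_levels, dtype=np.int64)
    mgl = 0.0
    for q in qflat:
        counts[q - 1] += 1
        mgl += q
    mgl /= n
    entropy = 0.0
    uniformity = 0.0
    for c in counts:
        if c > 0:
            p = c / n
            entropy -= p * np.log2(p)
            uniformity += p * p
    out[0] = mean
    out[1] = sd
    out[2] = median
    out[3] = mn
    out[4] = mx
    out[5] = var
    out[6] = skew
    out[7] = kurt
    out[8] = energy
    out[9] = entropy
    out[10] = uniformity
    out[11] = rms
    out[12] = mgl


def first_order_features(patch, n_levels: int = 32) -> dict:
    """The 13 first-order statistics of a raw-intensity patch."""
    patch = np.ascontiguousarray(patch, dtype=np.float64)
    if patch.size == 0:
        raise ValueError("empty patch")
    q = quantize(patch, n_levels)
    out = np.empty(13)
    _first_order_kernel(patch.ravel(), q.ravel(), n_levels, out)
    return dict(zip(FIRST_ORDER_NAMES, out))


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

@njit(cache=False)
def _glcm_kernel(q, n_levels, offsets):
    """Symmetric co-occurrence counts summed over offsets, normalized."""
    a, b, c = q.shape
    P = np.zeros((n_levels, n_levels))
    for o in range(offsets.shape[0]):
        di, dj, dk = offsets[o, 0], offsets[o, 1], offsets[o, 2]
        for i in range(a):
            i2 = i + di
            if i2 < 0 or i2 >= a:
                continue
            for j in range(b):
                j2 = j + dj
                if j2 < 0 or j2 >= b:
                    continue
                for k in range(c):
                    k2 = k + dk
                    if k2 < 0 or k2 >= c:
                        continue
                    g1 = q[i, j, k] - 1
                    g2 = q[i2, j2, k2] - 1
                    P[g1, g2] += 1.0
                    P[g2, g1] += 1.0
    s = P.sum()
    if s > 0.0:
        P /= s
    return P


@njit(cache=False)
def _glcm_features_kernel(P, out):
    """21 GLCM statistics of a normalized symmetric matrix -> out[0:21]."""
    ng = P.shape[0]
    px = np.zeros(ng)
    for i in range(ng):
        for j in range(ng):
            px[i] += P[i, j]
    mu = 0.0
    for i in range(ng):
        mu += (i + 1) * px[i]
    sig2 = 0.0
    for i in range(ng):
        d = (i + 1) - mu
        sig2 += d * d * px[i]
    sig = np.sqrt(sig2)

    acorr = 0.0
    contrast = 0.0
    corr_num = 0.0
    dissim = 0.0
    energy = 0.0
    entropy = 0.0
    hom_m = 0.0
    hom_p = 0.0
    sos = 0.0
    cshade = 0.0
    cprom = 0.0
    idn = 0.0
    maxp = 0.0
    sxy = np.zeros(2 * ng - 1)  # index i+j-2, levels sum 2..2ng
    dxy = np.zeros(ng)  # index |i-j|
    for i in range(ng):
        for j in range(ng):
            p = P[i, j]
            li = float(i + 1)
            lj = float(j + 1)
            ad = abs(li - lj)
            acorr += li * lj * p
            contrast += (li - lj) * (li - lj) * p
            corr_num += (li - mu) * (lj - mu) * p
            dissim += ad * p
            energy += p * p
            if p > 0.0:
                entropy -= p * np.log2(p)
            hom_m += p / (1.0 + ad)
            hom_p += p / (1.0 + (li - lj) * (li - lj))
            sos += (li - mu) * (li - mu) * p
            cs = li + lj - 2.0 * mu
            cshade += cs * cs * cs * p
            cprom += cs * cs * cs * cs * p
            idn += p / (1.0 + ad / ng)
            if p > maxp:
                maxp = p
            sxy[i + j] += p
            dxy[int(ad)] += p
    if sig > 0.0:
        corr_m = corr_num / (sig * sig)
        corr_p = (acorr - mu * mu) / (sig * sig)
    else:
        corr_m = 0.0
        corr_p = 0.0
    sum_avg = 0.0
    sum_ent = 0.0
    for k in range(2 * ng - 1):
        s = sxy[k]
        sum_avg += (k + 2) * s
        if s > 0.0:
            sum_ent -= s * np.log2(s)
    sum_var = 0.0
    for k in range(2 * ng - 1):
        d = (k + 2) - sum_avg
        sum_var += d * d * sxy[k]
    diff_avg = 0.0
    diff_ent = 0.0
    for k in range(ng):
        d = dxy[k]
        diff_avg += k * d
        if d > 0.0:
            diff_ent -= d * np.log2(d)
    diff_var = 0.0
    for k in range(ng):
        diff_var += (k - diff_avg) * (k - diff_avg) * dxy[k]
    # information measures of correlation (entropies in bits)
    hx = 0.0
    for i in range(ng):
        if px[i] > 0.0:
            hx -= px[i] * np.log2(px[i])
    hxy1 = 0.0
    hxy2 = 0.0
    for i in range(ng):
        for j in range(ng):
            pipj = px[i] * px[j]
            if pipj > 0.0:
                lg = np.log2(pipj)
                hxy1 -= P[i, j] * lg
                hxy2 -= pipj * lg
    if hx > 0.0:
        imc1 = (entropy - hxy1) / hx
    else:
        imc1 = 0.0
    arg = 1.0 - np.exp(-2.0 * _LN2 * (hxy2 - entropy))
    if arg < 0.0:
        arg = 0.0
    imc2 = np.sqrt(arg)

    out[0] = acorr
    out[1] = contrast
    out[2] = corr_m
    out[3] = corr_p
    out[4] = cprom
    out[5] = cshade
    out[6] = dissim
    out[7] = energy
    out[8] = entropy
    out[9] = hom_m
    out[10] = hom_p
    out[11] = sos
    out[12] = sum_var
    out[13] = sum_ent
    out[14] = diff_var
    out[15] = diff_ent
    out[16] = imc1
    out[17] = imc2
    out[18] = idn
    out[19] = maxp
    out[20] = sum_avg


def glcm_matrix(qpatch, offsets=None, symmetric: bool = True) -> np.ndarray:
    """Normalized symmetric gray-level co-occurrence matrix of a quantized patch.

    Counts level pairs at every offset, adds the transposed pair
    (symmetrization), sums over offsets and normalizes to total 1.  A patch
    with no valid pair (single voxel) yields the all-zero matrix.
    """
    if not symmetric:
        raise NotImplementedError("only the symmetric convention is supported")
    q = np.ascontiguousarray(qpatch, dtype=np.int64)
    if q.ndim != 3:
        raise ValueError("quantized patch must be 3D")
    if q.min() < 1:
        raise ValueError("quantized levels start at 1")
    n_levels = int(q.max())
    if offsets is None:
        offsets = directions_13()
    offsets = np.ascontiguousarray(offsets, dtype=np.int64)
    if np.any(np.all(offsets == 0, axis=1)):
        raise ValueError("offsets must be nonzero")
    return _glcm_kernel(q, n_levels, offsets)


def glcm_features(P) -> dict:
    """The 21 co-occurrence statistics of a normalized GLCM."""
    P = np.ascontiguousarray(P, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("GLCM must be square")
    out = np.empty(21)
    _glcm_features_kernel(P, out)
    return dict(zip(GLCM_NAMES, out))


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

@njit(cache=False)
def _glrlm_kernel(q, n_levels, directions):
    """Maximal-run counts R[level-1, length-1], summed over directions."""
    a, b, c = q.shape
    lmax = a
    if b > lmax:
        lmax = b
    if c > lmax:
        lmax = c
    R = np.zeros((n_levels, lmax))
    for d in range(directions.shape[0]):
        di, dj, dk = directions[d, 0], directions[d, 1], directions[d, 2]
        for i in range(a):
            for j in range(b):
                for k in range(c):
                    g = q[i, j, k]
                    # run start: predecessor outside patch or different level
                    pi, pj, pk = i - di, j - dj, k - dk
                    if (
                        0 <= pi < a
                        and 0 <= pj < b
                        and 0 <= pk < c
                        and q[pi, pj, pk] == g
                    ):
                        continue
                    length = 1
                    ni, nj, nk = i + di, j + dj, k + dk
                    while (
                        0 <= ni < a
                        and 0 <= nj < b
                        and 0 <= nk < c
                        and q[ni, nj, nk] == g
                    ):
                        length += 1
                        ni += di
                        nj += dj
                        nk += dk
                    R[g - 1, length - 1] += 1.0
    return R


@njit(cache=False)
def _glrlm_features_kernel(R, out):
    """8 run-length statistics -> out[0:8]."""
    ng, lmax = R.shape
    nr = 0.0
    npx = 0.0  # total voxel-length over all runs (= n_dirs * patch size)
    sre = 0.0
    lre = 0.0
    lgle = 0.0
    hgle = 0.0
    for g in range(ng):
        for l in range(lmax):
            r = R[g, l]
            if r == 0.0:
                continue
            length = float(l + 1)
            level = float(g + 1)
            nr += r
            npx += r * length
            sre += r / (length * length)
            lre += r * length * length
            lgle += r / (level * level)
            hgle += r * level * level
    gln = 0.0
    for g in range(ng):
        row = 0.0
        for l in range(lmax):
            row += R[g, l]
        gln += row * row
    rln = 0.0
    for l in range(lmax):
        col = 0.0
        for g in range(ng):
            col += R[g, l]
        rln += col * col
    out[0] = sre / nr
    out[1] = lre / nr
    out[2] = gln / nr
    out[3] = nr / npx
    out[4] = rln / nr
    out[5] = lgle / nr
    out[6] = hgle / nr
    out[7] = rln / (nr * nr)


def glrlm_matrix(qpatch, directions=None) -> np.ndarray:
    """Gray-level run-length matrix of a quantized patch, summed over directions.

    R[g-1, l-1] counts the maximal runs of level g and length l; per
    direction the identity sum_{g,l} R_d(g,l) * l = patch voxel count holds.
    """
    q = np.ascontiguousarray(qpatch, dtype=np.int64)
    if q.ndim != 3:
        raise ValueError("quantized patch must be 3D")
    if q.min() < 1:
        raise ValueError("quantized levels start at 1")
    n_levels = int(q.max())
    if directions is None:
        directions = directions_13()
    directions = np.ascontiguousarray(directions, dtype=np.int64)
    return _glrlm_kernel(q, n_levels, directions)


def glrlm_features(R) -> dict:
    """The 8 run-length statistics of a run-length matrix."""
    R = np.ascontiguousarray(R, dtype=np.float64)
    if R.sum() == 0:
        raise ValueError("all-zero run-length matrix")
    out = np.empty(8)
    _glrlm_features_kernel(R, out)
    return dict(zip(GLRLM_NAMES, out))
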
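"""Independent brute-force oracles for the radiomics feature definitions.

Everything here is a deliberately naive pure-Python/numpy transcription of
the feature definitions — dict-based pair counting, line-scan run
enumeration, formula-by-formula statistics — kept free of any code shared
with the package kernels so the two paths can disagree.
"""

from collections import Counter
from itertools import product

import numpy as np
from scipy import stats as sps

DIRECTIONS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

LN2 = np.log(2.0)


def log2_safe(x):
    return np.log(x) / LN2


def oracle_quantize(patch, n_levels):
    patch = np.asarray(patch, dtype=float)
    mn, mx = patch.min(), patch.max()
    if mx == mn or n_levels == 1:
        return np.ones(patch.shape, dtype=int)
    lev = np.floor((patch - mn) / (mx - mn) * n_levels).astype(int) + 1
    return np.minimum(lev, n_levels)


def oracle_first_order(patch, n_levels=32):
    x = np.asarray(patch, dtype=float).ravel()
    n = x.size
    var = ((x - x.mean()) ** 2).sum() / n  # population
    sd = np.sqrt(var)
    skew = float(sps.skew(x)) if sd > 0 else 0.0
    kurt = float(sps.kurtosis(x, fisher=False)) if sd > 0 else 0.0
    q = oracle_quantize(x, n_levels)
    counts = Counter(q.tolist())
    probs = [c / n for c in counts.values()]
    entropy = -sum(p * log2_safe(p) for p in probs)
    uniformity = sum(p * p for p in probs)
    return {
        "mean": x.mean(),
        "std": sd,
        "median": float(np.median(x)),
        "min": x.min(),
        "max": x.max(),
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float((x**2).sum()),
        "entropy": entropy,
        "uniformity": uniformity,
        "rms": float(np.sqrt((x**2).mean())),
        "mean_gray_level": float(q.mean()),
    }


def oracle_glcm(qpatch, offsets=DIRECTIONS_13, n_levels=None):
    """Symmetrized pair counts via explicit voxel-pair enumeration."""
    q = np.asarray(qpatch)
    ng = int(q.max()) if n_levels is None else n_levels
    counts = Counter()
    shape = q.shape
    for off in offsets:
        for idx in product(*(range(s) for s in shape)):
            nbr = tuple(i + o for i, o in zip(idx, off))
            if all(0 <= v < s for v, s in zip(nbr, shape)):
                a, b = int(q[idx]), int(q[nbr])
                counts[(a, b)] += 1
                counts[(b, a)] += 1
    P = np.zeros((ng, ng))
    for (a, b), c in counts.items():
        P[a - 1, b - 1] = c
    total = P.sum()
    return P / total if total > 0 else P


def oracle_glcm_features(P):
    """Formula-by-formula transcription of the 21 co-occurrence statistics."""
    P = np.asarray(P, dtype=float)
    ng = P.shape[0]
    i = np.arange(1, ng + 1)[:, None] * np.ones((1, ng))
    j = np.ones((ng, 1)) * np.arange(1, ng + 1)[None, :]
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mux = float((np.arange(1, ng + 1) * px).sum())
    muy = float((np.arange(1, ng + 1) * py).sum())
    sigx = float(np.sqrt(((np.arange(1, ng + 1) - mux) ** 2 * px).sum()))
    sigy = float(np.sqrt(((np.arange(1, ng + 1) - muy) ** 2 * py).sum()))
    nz = P > 0
    entropy = float(-(P[nz] * log2_safe(P[nz])).sum())
    # sum and difference distributions
    sxy = {}
    dxy = {}
    for a in range(1, ng + 1):
        for b in range(1, ng + 1):
            sxy[a + b] = sxy.get(a + b, 0.0) + P[a - 1, b - 1]
            dxy[abs(a - b)] = dxy.get(abs(a - b), 0.0) + P[a - 1, b - 1]
    sum_avg = sum(k * v for k, v in sxy.items())
    sum_var = sum((k - sum_avg) ** 2 * v for k, v in sxy.items())
    sum_ent = -sum(v * log2_safe(v) for v in sxy.values() if v > 0)
    diff_avg = sum(k * v for k, v in dxy.items())
    diff_var = sum((k - diff_avg) ** 2 * v for k, v in dxy.items())
    diff_ent = -sum(v * log2_safe(v) for v in dxy.values() if v > 0)
    hx = float(-(px[px > 0] * log2_safe(px[px > 0])).sum())
    hy = float(-(py[py > 0] * log2_safe(py[py > 0])).sum())
    pxpy = px[:, None] * py[None, :]
    m = pxpy > 0
    hxy1 = float(-(P[m] * log2_safe(pxpy[m])).sum())
    hxy2 = float(-(pxpy[m] * log2_safe(pxpy[m])).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * LN2 * (hxy2 - entropy))))
    sig_ok = sigx > 0 and sigy > 0
    return {
        "autocorrelation": float((i * j * P).sum()),
        "contrast": float(((i - j) ** 2 * P).sum()),
        "correlation_m": float(((i - mux) * (j - muy) * P).sum() / (sigx * sigy))
        if sig_ok
        else 0.0,
        "correlation_p": float(((i * j * P).sum() - mux * muy) / (sigx * sigy))
        if sig_ok
        else 0.0,
        "cluster_prominence": float(((i + j - mux - muy) ** 4 * P).sum()),
        "cluster_shade": float(((i + j - mux - muy) ** 3 * P).sum()),
        "dissimilarity": float((np.abs(i - j) * P).sum()),
        "energy": float((P**2).sum()),
        "entropy": entropy,
        "homogeneity_m": float((P / (1.0 + np.abs(i - j))).sum()),
        "homogeneity_p": float((P / (1.0 + (i - j) ** 2)).sum()),
        "sum_of_squares": float(((i - mux) ** 2 * P).sum()),
        "sum_variance": float(sum_var),
        "sum_entropy": float(sum_ent),
        "difference_variance": float(diff_var),
        "difference_entropy": float(diff_ent),
        "imc1": float(imc1),
        "imc2": float(imc2),
        "inverse_difference_normalized": float((P / (1.0 + np.abs(i - j) / ng)).sum()),
        "maximum_probability": float(P.max()),
        "sum_average": float(sum_avg),
    }


def _lines_through(shape, direction):
    """All maximal lattice lines through a box along a direction."""
    starts = []
    for idx in product(*(range(s) for s in shape)):
        prev = tuple(i - d for i, d in zip(idx, direction))
        if not all(0 <= v < s for v, s in zip(prev, shape)):
            starts.append(idx)
    lines = []
    for s0 in starts:
        line = []
        cur = s0
        while all(0 <= v < s for v, s in zip(cur, shape)):
            line.append(cur)
            cur = tuple(i + d for i, d in zip(cur, direction))
        lines.append(line)
    return lines


def oracle_glrlm(qpatch, directions=DIRECTIONS_13, n_levels=None):
    """Run counts by scanning every lattice line, direction by direction."""
    q = np.asarray(qpatch)
    ng = int(q.max()) if n_levels is None else n_levels
    lmax = max(q.shape)
    R = np.zeros((ng, lmax))
    for d in directions:
        for line in _lines_through(q.shape, d):
            vals = [int(q[idx]) for idx in line]
            pos = 0
            while pos < len(vals):
                end = pos
                while end + 1 < len(vals) and vals[end + 1] == vals[pos]:
                    end += 1
                R[vals[pos] - 1, end - pos] += 1
                pos = end + 1
    return R


def oracle_glrlm_features(R):
    """Direct-summation transcription of the 8 run-length statistics."""
    R = np.asarray(R, dtype=float)
    ng, lmax = R.shape
    g = np.arange(1, ng + 1)[:, None]
    l = np.arange(1, lmax + 1)[None, :]
    nr = R.sum()
    npix = (R * l).sum()
    return {
        "short_run_emphasis": float((R / l**2).sum() / nr),
        "long_run_emphasis": float((R * l**2).sum() / nr),
        "gray_level_nonuniformity": float((R.sum(axis=1) ** 2).sum() / nr),
        "run_percentage": float(nr / npix),
        "run_length_nonuniformity": float((R.sum(axis=0) ** 2).sum() / nr),
        "low_gray_level_emphasis": float((R / g**2).sum() / nr),
        "high_gray_level_emphasis": float((R * g**2).sum() / nr),
        "run_length_nonuniformity_normalized": float(
            (R.sum(axis=0) ** 2).sum() / nr**2
        ),
    }


def oracle_patch(volume, coord, window=5, n_levels=32):
    """Clipped patch around a voxel (same support convention as the kernels)."""
    half = window // 2
    sl = tuple(
        slice(max(c - half, 0), min(c + half + 1, s))
        for c, s in zip(coord, volume.shape)
    )
    return np.asarray(volume[sl], dtype=float)


def oracle_voxel_features(volume, coord, window=5, n_levels=32):
    """The full 42-vector of one voxel, in registry order."""
    patch = oracle_patch(volume, coord, window, n_levels)
    q = oracle_quantize(patch, n_levels)
    fo = oracle_first_order(patch, n_levels)
    P = oracle_glcm(q, n_levels=n_levels)
    gf = oracle_glcm_features(P)
    R = oracle_glrlm(q, n_levels=n_levels)
    rf = oracle_glrlm_features(R)
    from periprog.radiomics.registry import (
        FIRST_ORDER_NAMES,
        GLCM_NAMES,
        GLRLM_NAMES,
    )

    vec = [fo[k] for k in FIRST_ORDER_NAMES]
    vec += [gf[k] for k in GLCM_NAMES]
    vec += [rf[k] for k in GLRLM_NAMES]
    return np.array(vec, dtype=float)
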
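"""Isotropic/anisotropic decomposition of the diffusion tensor.

Given the three eigenvalues of a fitted diffusion tensor, the tensor can be
split into an isotropic part (mean diffusivity times the identity) and the
anisotropic remainder.  The magnitudes of the two parts,

    MD = (l1 + l2 + l3) / 3
    p  = sqrt(3) * MD                    (norm of the isotropic component)
    q  = sqrt(sum_i (l_i - MD)**2)       (norm of the deviatoric component)
    FA = sqrt(3/2) * q / sqrt(sum_i l_i**2)

are the DTI-p and DTI-q maps used as two of the seven input modalities, and
satisfy the Pythagorean identity p**2 + q**2 = sum_i l_i**2.
"""

from __future__ import annotations

import numpy as np

__all__ = ["decompose_pq", "decompose_pq_volumes"]


def decompose_pq(eigenvalues):
    """Decompose diffusion-tensor eigenvalues into (p, q, FA, MD).

    Parameters
    ----------
    eigenvalues : array_like, shape (..., 3)
        Eigenvalue triples (any order), in diffusivity units (mm^2/s).
        Must be finite and non-negative; an all-zero triple is rejected
        because FA is undefined there.

    Returns
    -------
    p, q, fa, md : ndarray, shape (...)
        Isotropic magnitude, anisotropic magnitude, fractional anisotropy
        (dimensionless, in [0, 1]) and mean diffusivity.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.shape[-1] != 3:
        raise ValueError(f"expected eigenvalue triples (..., 3), got {lam.shape}")
    if not np.all(np.isfinite(lam)):
        raise ValueError("eigenvalues must be finite")
    if np.any(lam < 0):
        raise ValueError("negative eigenvalues are not valid diffusivities")
    sumsq = np.einsum("...i,...i->...", lam, lam)
    if np.any(sumsq == 0):
        raise ValueError("all-zero eigenvalue triple: FA is undefined")
    md = lam.mean(axis=-1)
    p = np.sqrt(3.0) * md
    dev = lam - md[..., None]
    q = np.sqrt(np.einsum("...i,...i->...", dev, dev))
    fa = np.sqrt(1.5) * q / np.sqrt(sumsq)
    return p, q, fa, md


def decompose_pq_volumes(l1, l2, l3, background="zero"):
    """Voxel-wise (p, q, FA, MD) maps from three eigenvalue volumes.

    All-zero voxels (outside the fitted brain) are common in eigenvalue
    maps; with ``background="zero"`` they yield 0 in every output map
    instead of raising, with ``background="raise"`` they are an error.
    """
    l1, l2, l3 = (np.asarray(a, dtype=float) for a in (l1, l2, l3))
    if not (l1.shape == l2.shape == l3.shape):
        raise ValueError("eigenvalue volumes must share a grid")
    lam = np.stack([l1, l2, l3], axis=-1)
    zero = np.all(lam == 0, axis=-1)
    if background == "raise" or not zero.any():
        return decompose_pq(lam)
    if background != "zero":
        raise ValueError("background must be 'zero' or 'raise'")
    out = [np.zeros(l1.shape) for _ in range(4)]
    if (~zero).any():
        vals = decompose_pq(lam[~zero])
        for o, v in zip(out, vals):
            o[~zero] = v
    return tuple(out)
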
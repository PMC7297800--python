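"""Voxel-wise feature-table extraction.

For every voxel of a target mask, a cubic neighborhood (default 5x5x5,
clipped at the volume border) is taken from each of the 7 modality volumes
and the 42 per-modality statistics are computed, giving one 294-column row
per voxel.  Rows carry the voxel index, an optional binary progression
label and a subject id, matching the layout the classifier trains on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numba import njit

from .features import (
    _first_order_kernel,
    _glcm_features_kernel,
    _glcm_kernel,
    _glrlm_features_kernel,
    _glrlm_kernel,
    _quantize_kernel,
    directions_13,
)
from .registry import MODALITIES, feature_registry

__all__ = ["extract_modality_features", "voxelwise_feature_table"]

N_PER_MODALITY = 42  # 13 first order + 21 GLCM + 8 GLRLM


@njit(cache=False)
def _modality_kernel(vol, coords, half, n_levels, offsets, out):
    ni, nj, nk = vol.shape
    for r in range(coords.shape[0]):
        i, j, k = coords[r, 0], coords[r, 1], coords[r, 2]
        i0 = max(i - half, 0)
        i1 = min(i + half + 1, ni)
        j0 = max(j - half, 0)
        j1 = min(j + half + 1, nj)
        k0 = max(k - half, 0)
        k1 = min(k + half + 1, nk)
        patch = np.ascontiguousarray(vol[i0:i1, j0:j1, k0:k1])
        q = _quantize_kernel(patch, n_levels)
        _first_order_kernel(patch.ravel(), q.ravel(), n_levels, out[r, 0:13])
        P = _glcm_kernel(q, n_levels, offsets)
        _glcm_features_kernel(P, out[r, 13:34])
        R = _glrlm_kernel(q, n_levels, offsets)
        _glrlm_features_kernel(R, out[r, 34:42])


def extract_modality_features(volume, coords, window: int = 5, n_levels: int = 32):
    """42 per-voxel statistics of one modality at the given voxel indices.

    Returns an array of shape ``(len(coords), 42)`` in registry order
    (13 first-order, 21 GLCM, 8 GLRLM).
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    vol = np.ascontiguousarray(volume, dtype=np.float64)
    if vol.ndim != 3:
        raise ValueError("volume must be 3D")
    coords = np.ascontiguousarray(coords, dtype=np.int64)
    out = np.empty((coords.shape[0], N_PER_MODALITY))
    _modality_kernel(vol, coords, window // 2, n_levels, directions_13(), out)
    return out


def voxelwise_feature_table(
    volumes,
    mask,
    window: int = 5,
    n_levels: int = 32,
    labels=None,
    subject_id=None,
) -> pd.DataFrame:
    """Extract the 294-feature table over every voxel of ``mask``.

    Parameters
    ----------
    volumes : mapping modality name -> 3D array, or MultimodalVolume
        Must contain all 7 modalities on one grid.
    mask : boolean 3D array
        Target voxels (one output row each).
    labels : boolean 3D array, optional
        Per-voxel progression flag; stored in the ``label`` column.
    """
    if hasattr(volumes, "data"):  # MultimodalVolume
        volumes = volumes.data
    missing = [m for m in MODALITIES if m not in volumes]
    if missing:
        raise ValueError(f"missing modalities: {missing}")
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)
    if coords.shape[0] == 0:
        raise ValueError("empty extraction mask")
    reg = feature_registry()
    blocks = [
        extract_modality_features(volumes[m], coords, window, n_levels)
        for m in MODALITIES
    ]
    values = np.hstack(blocks)
    if not np.all(np.isfinite(values)):
        raise AssertionError("non-finite feature value escaped the degenerate rules")
    df = pd.DataFrame(values, columns=reg.names)
    df.insert(0, "k", coords[:, 2])
    df.insert(0, "j", coords[:, 1])
    df.insert(0, "i", coords[:, 0])
    if labels is not None:
        lab = np.asarray(labels, dtype=bool)
        df.insert(3, "label", lab[mask].astype(np.int64))
    if subject_id is not None:
        df.insert(0, "subject", subject_id)
    return df
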
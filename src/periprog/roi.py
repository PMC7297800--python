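"""Region-of-interest geometry on the preoperative grid.

The study regions are: the contrast-enhancing (CE) lesion, the peritumoral
progression region (the future-recurrence lesion minus the CE lesion),
four non-progression distance bands at 5/10/15/20 mm from the CE surface
(each excluding the progression region), and a contralateral
normal-appearing white matter (NAWM) control obtained by mirroring the
abnormal region across the midsagittal plane.

Distances are physical (mm), via a spacing-aware Euclidean distance
transform; bands are half-open intervals (d_{k-1}, d_k] measured from the
CE mask surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "RoiSet",
    "progression_roi",
    "shell_masks",
    "nawm_mask",
    "build_roi_set",
    "roi_label_volume",
]

DEFAULT_DISTANCES_MM = (5.0, 10.0, 15.0, 20.0)


@dataclass
class RoiSet:
    """The complete study ROI collection for one subject."""

    ce_mask: np.ndarray
    progression_roi: np.ndarray
    shells: dict  # outer distance (mm) -> boolean mask
    nawm_mask: np.ndarray
    brain_mask: np.ndarray
    voxel_spacing_mm: tuple = (1.0, 1.0, 1.0)

    def labeled_rois(self):
        """(label, mask) pairs: CE, progression, the four bands, NAWM."""
        out = [("CE", self.ce_mask), ("progression", self.progression_roi)]
        out += [(f"NP-{int(d)}", m) for d, m in sorted(self.shells.items())]
        out.append(("NAWM", self.nawm_mask))
        return out

    @property
    def peritumoral_mask(self) -> np.ndarray:
        """Progression plus all non-progression bands (classifier support)."""
        m = self.progression_roi.copy()
        for s in self.shells.values():
            m |= s
        return m


def _as_mask(a, name):
    m = np.asarray(a)
    if m.dtype != bool:
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} must be binary")
        m = m.astype(bool)
    return m


def progression_roi(progression_mask, ce_mask) -> np.ndarray:
    """Progression ROI: the progression lesion minus the CE lesion."""
    prog = _as_mask(progression_mask, "progression_mask")
    ce = _as_mask(ce_mask, "ce_mask")
    if prog.shape != ce.shape:
        raise ValueError("masks must share a grid")
    return prog & ~ce


def surface_distance_mm(ce_mask, spacing) -> np.ndarray:
    """Euclidean distance (mm) from each voxel to the CE mask, 0 inside."""
    ce = _as_mask(ce_mask, "ce_mask")
    if not ce.any():
        raise ValueError("empty CE mask")
    return ndimage.distance_transform_edt(~ce, sampling=spacing)


def shell_masks(
    ce_mask,
    progression_roi_mask,
    brain_mask,
    distances_mm=DEFAULT_DISTANCES_MM,
    spacing=(1.0, 1.0, 1.0),
) -> dict:
    """Non-progression distance bands around the CE lesion.

    Band k holds the voxels with CE-surface distance in (d_{k-1}, d_k]
    (d_0 = 0), inside the brain, excluding the CE lesion and the
    progression ROI.  Returns ``{outer distance: mask}``.
    """
    d = np.asarray(distances_mm, dtype=float)
    if d.size == 0 or np.any(d <= 0) or np.any(np.diff(d) <= 0):
        raise ValueError("distances must be strictly increasing and positive")
    ce = _as_mask(ce_mask, "ce_mask")
    prog = _as_mask(progression_roi_mask, "progression_roi")
    brain = _as_mask(brain_mask, "brain_mask")
    dist = surface_distance_mm(ce, spacing)
    allowed = brain & ~ce & ~prog
    shells = {}
    lo = 0.0
    for hi in d:
        shells[float(hi)] = allowed & (dist > lo) & (dist <= hi)
        lo = hi
    return shells


def nawm_mask(ce_mask, progression_mask, brain_mask, midline_axis: int = 0,
              spacing=(1.0, 1.0, 1.0), envelope_mm: float = 20.0) -> np.ndarray:
    """Contralateral NAWM control region.

    Mirrors the abnormal region (CE lesion, progression lesion and the
    surrounding ``envelope_mm`` peritumoral envelope) across the
    midsagittal plane of the grid, keeps what falls inside the brain and
    removes any overlap with the ipsilateral abnormal masks.  Warns when
    part of the mirrored region falls outside the brain.
    """
    ce = _as_mask(ce_mask, "ce_mask")
    prog = _as_mask(progression_mask, "progression_mask")
    brain = _as_mask(brain_mask, "brain_mask")
    if not ce.any():
        raise ValueError("empty CE mask")
    dist = surface_distance_mm(ce, spacing)
    abnormal = ce | prog
    region = (abnormal | (dist <= envelope_mm)) & brain
    mirrored = np.flip(region, axis=midline_axis)
    out = mirrored & brain & ~abnormal
    n_lost = int(mirrored.sum() - (mirrored & brain).sum())
    if n_lost:
        warnings.warn(
            f"{n_lost} mirrored voxels fall outside the brain mask; "
            "NAWM restricted to the intersection",
            stacklevel=2,
        )
    return out


def build_roi_set(
    ce_mask,
    progression_mask,
    brain_mask,
    spacing=(1.0, 1.0, 1.0),
    distances_mm=DEFAULT_DISTANCES_MM,
    midline_axis: int = 0,
) -> RoiSet:
    """Assemble the full ROI set from the three primary masks."""
    prog_roi = progression_roi(progression_mask, ce_mask)
    shells = shell_masks(ce_mask, prog_roi, brain_mask, distances_mm, spacing)
    nawm = nawm_mask(ce_mask, progression_mask, brain_mask, midline_axis,
                     spacing, envelope_mm=float(np.max(distances_mm)))
    return RoiSet(
        ce_mask=_as_mask(ce_mask, "ce_mask"),
        progression_roi=prog_roi,
        shells=shells,
        nawm_mask=nawm,
        brain_mask=_as_mask(brain_mask, "brain_mask"),
        voxel_spacing_mm=tuple(spacing),
    )


def roi_label_volume(roi_set: RoiSet):
    """Serialize the band set as one labeled volume plus a JSON-able legend.

    0 = background, 1..4 = the distance bands in increasing order.
    """
    labels = np.zeros(roi_set.ce_mask.shape, dtype=np.int16)
    legend = {"0": "none"}
    for idx, (hi, m) in enumerate(sorted(roi_set.shells.items()), start=1):
        labels[m] = idx
        legend[str(idx)] = f"band <= {hi} mm"
    return labels, legend
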
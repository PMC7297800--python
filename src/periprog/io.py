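"""NIfTI and sidecar serialization for phantom subjects and maps."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import MODALITIES, EffectRow, MultimodalVolume, PhantomSubject

__all__ = [
    "affine_from_spacing",
    "save_volume",
    "load_volume",
    "save_subject",
    "load_subject",
    "save_cohort_manifest",
]


def affine_from_spacing(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_volume(array, spacing, path):
    """Write a 3D array as NIfTI with a diagonal spacing affine."""
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float32),
                          affine_from_spacing(spacing))
    nib.save(img, str(path))


def load_volume(path):
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata()), spacing


def _safe(name: str) -> str:
    return name.replace("-", "")


def save_subject(subject: PhantomSubject, directory, effect_table=None):
    """One NIfTI per modality + NIfTI masks + a JSON ground-truth sidecar."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    spacing = subject.volumes.voxel_spacing_mm
    for m in MODALITIES:
        save_volume(subject.volumes[m], spacing, d / f"{_safe(m)}.nii")
    for name, mask in (
        ("ce_mask", subject.ce_mask),
        ("progression_mask", subject.progression_mask),
        ("brain_mask", subject.brain_mask),
    ):
        save_volume(mask.astype(np.uint8), spacing, d / f"{name}.nii")
    sidecar = {
        "subject_id": subject.subject_id,
        "core_radius_mm": subject.core_radius_mm,
        "cap_direction": subject.cap_direction.tolist(),
        "voxel_spacing_mm": list(spacing),
    }
    if effect_table is not None:
        sidecar["effect_table"] = {m: asdict(r) for m, r in effect_table.items()}
    (d / "truth.json").write_text(json.dumps(sidecar, indent=1))


def load_subject(directory) -> PhantomSubject:
    d = Path(directory)
    sidecar = json.loads((d / "truth.json").read_text())
    spacing = tuple(sidecar["voxel_spacing_mm"])
    data = {m: load_volume(d / f"{_safe(m)}.nii")[0] for m in MODALITIES}
    masks = {
        name: load_volume(d / f"{name}.nii")[0].astype(bool)
        for name in ("ce_mask", "progression_mask", "brain_mask")
    }
    return PhantomSubject(
        subject_id=sidecar["subject_id"],
        volumes=MultimodalVolume(data, spacing),
        ce_mask=masks["ce_mask"],
        progression_mask=masks["progression_mask"],
        brain_mask=masks["brain_mask"],
        core_radius_mm=sidecar["core_radius_mm"],
        cap_direction=np.array(sidecar["cap_direction"]),
    )


def save_cohort_manifest(subjects, path):
    """CSV manifest of a generated cohort."""
    import pandas as pd

    rows = [
        {
            "subject_id": s.subject_id,
            "core_radius_mm": s.core_radius_mm,
            "n_ce_voxels": int(s.ce_mask.sum()),
            "n_progression_voxels": int(s.progression_mask.sum()),
            "n_brain_voxels": int(s.brain_mask.sum()),
        }
        for s in subjects
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
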
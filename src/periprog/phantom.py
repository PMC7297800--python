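"""Synthetic multimodal MR phantom cohorts.

Each phantom subject carries the seven co-registered modality volumes
(T1C, FLAIR, ADC, FA, DTI-p, DTI-q, rCBV) on one grid, together with a
contrast-enhancing (CE) tumor core, a future-progression region and a
brain mask.  The geometry is deliberately simple — an ellipsoidal brain, a
spherical CE core placed off the midline, and a directional spherical-cap
progression region abutting the core — because no tested quantity depends
on lesion shape.

The intensity model per modality is

    value = baseline + shift * 1[progression] + 1.5 * shift * 1[CE core]
            + spatially smoothed Gaussian noise,

with the default shift signs taken from the group contrasts the method is
built to detect: FLAIR, T1C and rCBV elevated in future-progression
tissue, ADC, DTI-p and FA depressed, DTI-q null.  Default shift magnitude
is 0.8 x the noise standard deviation for every affected modality.
Intensities are arbitrary units (plausible scales, no acquisition physics).

Everything is deterministic given (seed, subject_index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "EffectRow",
    "PhantomParams",
    "MultimodalVolume",
    "PhantomSubject",
    "GeometryError",
    "default_effect_table",
    "zero_effect_table",
    "generate_subject",
    "generate_cohort",
]

MODALITIES = ("T1C", "FLAIR", "ADC", "FA", "DTI-p", "DTI-q", "rCBV")


class GeometryError(ValueError):
    """Core or progression region does not fit inside the brain mask."""


@dataclass(frozen=True)
class EffectRow:
    """Per-modality intensity model: baseline, progression shift, noise sd."""

    baseline: float
    shift: float
    noise_sd: float

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def default_effect_table() -> dict:
    """Default per-modality effects (signs of the reported group contrasts).

    FLAIR/T1C/rCBV shifted up in progression tissue, ADC/DTI-p/FA shifted
    down, DTI-q unshifted; every nonzero shift is 0.8 x the noise sd.
    """
    return {
        "T1C": EffectRow(95.0, +8.0, 10.0),
        "FLAIR": EffectRow(110.0, +8.0, 10.0),
        "ADC": EffectRow(1.2, -0.12, 0.15),
        "FA": EffectRow(0.40, -0.064, 0.08),
        "DTI-p": EffectRow(1.9, -0.16, 0.20),
        "DTI-q": EffectRow(1.0, 0.0, 0.15),
        "rCBV": EffectRow(2.5, +0.48, 0.60),
    }


def zero_effect_table() -> dict:
    """The default table with every progression shift set to zero (null)."""
    return {
        m: EffectRow(r.baseline, 0.0, r.noise_sd)
        for m, r in default_effect_table().items()
    }


@dataclass
class PhantomParams:
    """Cohort-level phantom configuration.

    The defaults define the desk-scale study conditions: a 48 mm-cube grid
    at 1 mm isotropic spacing, a 7 mm CE core 5 mm off the midline, an
    8 mm-thick progression cap with 75 deg half-angle, 2 mm-FWHM smoothed
    noise, and the default effect table.
    """

    grid_shape: tuple = (48, 48, 48)
    voxel_spacing_mm: tuple = (1.0, 1.0, 1.0)
    core_radius_mm: float = 7.0
    progression_extent_mm: float = 8.0
    effect_table: dict = field(default_factory=default_effect_table)
    smoothing_fwhm_mm: float = 2.0
    n_subjects: int = 10
    seed: int = 0
    # geometry knobs (fixed across subjects)
    core_offset_mm: float = 5.0
    cap_half_angle_deg: float = 75.0
    radius_jitter: float = 0.15
    brain_axis_fraction: float = 0.46
    midline_axis: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if self.core_radius_mm <= 0 or self.progression_extent_mm <= 0:
            raise ValueError("core radius and progression extent must be positive")
        missing = [m for m in MODALITIES if m not in self.effect_table]
        if missing:
            raise ValueError(f"effect table missing modalities: {missing}")


@dataclass
class MultimodalVolume:
    """Stack of co-registered scalar 3D maps plus voxel spacing."""

    data: dict  # modality name -> 3D float array
    voxel_spacing_mm: tuple

    def __getitem__(self, modality):
        return self.data[modality]


@dataclass
class PhantomSubject:
    """One synthetic subject with ground truth."""

    subject_id: str
    volumes: MultimodalVolume
    ce_mask: np.ndarray
    progression_mask: np.ndarray
    brain_mask: np.ndarray
    core_radius_mm: float
    cap_direction: np.ndarray

    @property
    def truth_labels(self) -> np.ndarray:
        """Per-voxel future-progression flag (the progression mask)."""
        return self.progression_mask


def _coordinate_grid_mm(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _smoothed_noise(rng, shape, spacing, fwhm_mm):
    """Unit-variance spatially correlated Gaussian field."""
    noise = rng.standard_normal(shape)
    if fwhm_mm > 0:
        sigma_vox = [fwhm_mm / 2.3548200450309493 / s for s in spacing]
        noise = ndimage.gaussian_filter(noise, sigma=sigma_vox)
        sd = noise.std()
        if sd > 0:
            noise /= sd
    return noise


def generate_subject(params: PhantomParams, subject_index: int) -> PhantomSubject:
    """Generate one phantom subject, deterministic given (seed, subject_index)."""
    rng = np.random.default_rng([params.seed, subject_index])
    shape = tuple(params.grid_shape)
    spacing = tuple(params.voxel_spacing_mm)
    grids = _coordinate_grid_mm(shape, spacing)
    center = np.array([(n - 1) * s / 2.0 for n, s in zip(shape, spacing)])

    # brain: axis-aligned ellipsoid
    semi = np.array([params.brain_axis_fraction * n * s for n, s in zip(shape, spacing)])
    brain = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi)) <= 1.0

    # subject-level variation: core radius, cap orientation, noise
    radius = params.core_radius_mm * (1.0 + params.radius_jitter * rng.uniform(-1, 1))
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)

    core_center = center.copy()
    core_center[params.midline_axis] += params.core_offset_mm
    delta = [g - c for g, c in zip(grids, core_center)]
    r = np.sqrt(sum(d * d for d in delta))
    ce = r <= radius

    # spherical cap: radial band (radius, radius + extent] within the cone
    # around `direction`
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = sum(d * u for d, u in zip(delta, direction)) / np.where(r > 0, r, np.inf)
    cap = (
        (r > radius)
        & (r <= radius + params.progression_extent_mm)
        & (cosang >= np.cos(np.deg2rad(params.cap_half_angle_deg)))
    )

    if not ce.any():
        raise GeometryError("CE core contains no voxel")
    if (ce & ~brain).any() or (cap & ~brain).any():
        raise GeometryError(
            "core or progression region extends outside the brain mask; "
            "shrink the lesion or enlarge the grid"
        )
    progression = cap & ~ce  # disjoint by construction (r > radius), kept explicit

    data = {}
    for m in MODALITIES:
        row = params.effect_table[m]
        vol = np.full(shape, row.baseline, dtype=np.float64)
        vol += row.shift * progression
        vol += 1.5 * row.shift * ce
        if row.noise_sd > 0:
            vol += row.noise_sd * _smoothed_noise(
                rng, shape, spacing, params.smoothing_fwhm_mm
            )
        data[m] = vol

    return PhantomSubject(
        subject_id=f"sub-{subject_index:03d}",
        volumes=MultimodalVolume(data, spacing),
        ce_mask=ce,
        progression_mask=progression,
        brain_mask=brain,
        core_radius_mm=float(radius),
        cap_direction=direction,
    )


def generate_cohort(params: PhantomParams) -> list:
    """Generate ``params.n_subjects`` phantom subjects."""
    if params.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    return [generate_subject(params, i) for i in range(params.n_subjects)]
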
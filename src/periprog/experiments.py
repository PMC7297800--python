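"""End-to-end phantom experiments.

These drivers chain the whole pipeline — phantom cohort, ROI geometry,
voxel-wise radiomics, classifier, group statistics — at desk scale.  They
are what the acceptance checks and the numbered analysis scripts run, so
the problem sizes here define the study conditions: 10 training + 4
external-validation subjects with about 3,600 sampled peritumoral voxels
each (~5e4 voxels in total) for parameter recovery, and 10 independent
8-subject null cohorts for the type-I calibration of the feature screen.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classifier import SplitSpec, external_validate, fit_from_table
from .network import TrainConfig, predict_proba
from .phantom import PhantomParams, default_effect_table, generate_cohort, zero_effect_table
from .radiomics.table import voxelwise_feature_table
from .roi import build_roi_set
from .stats import feature_screen, subject_feature_means

__all__ = [
    "subject_roi_set",
    "sample_voxels",
    "subject_feature_table",
    "cohort_feature_tables",
    "run_parameter_recovery",
    "run_null_calibration",
]


def subject_roi_set(subject):
    """The study ROI set of one phantom subject."""
    return build_roi_set(
        subject.ce_mask,
        subject.progression_mask,
        subject.brain_mask,
        spacing=subject.volumes.voxel_spacing_mm,
    )


def sample_voxels(progression_mask, nonprogression_mask, max_voxels, rng,
                  progression_fraction: float = 0.3):
    """Seeded subsample of labeled peritumoral voxels.

    Caps the row count at ``max_voxels`` with at most
    ``progression_fraction`` of the sample drawn from the progression
    region (fewer if the region is small), the rest from the
    non-progression bands.  Returns a boolean sampling mask.
    """
    prog_idx = np.flatnonzero(progression_mask.ravel())
    non_idx = np.flatnonzero(nonprogression_mask.ravel())
    n_prog = min(len(prog_idx), int(round(max_voxels * progression_fraction)))
    n_non = min(len(non_idx), max_voxels - n_prog)
    take = np.concatenate(
        [
            rng.choice(prog_idx, size=n_prog, replace=False),
            rng.choice(non_idx, size=n_non, replace=False),
        ]
    )
    out = np.zeros(progression_mask.size, dtype=bool)
    out[take] = True
    return out.reshape(progression_mask.shape)


def subject_feature_table(subject, roi_set=None, window=5, n_levels=32,
                          max_voxels=None, rng=None, progression_fraction=0.3):
    """Labeled 294-feature table over a subject's peritumoral voxels."""
    roi_set = roi_set or subject_roi_set(subject)
    nonprog = np.zeros(subject.ce_mask.shape, dtype=bool)
    for s in roi_set.shells.values():
        nonprog |= s
    prog = roi_set.progression_roi
    if max_voxels is not None:
        rng = rng or np.random.default_rng(0)
        mask = sample_voxels(prog, nonprog, max_voxels, rng, progression_fraction)
    else:
        mask = prog | nonprog
    return voxelwise_feature_table(
        subject.volumes, mask, window, n_levels,
        labels=prog, subject_id=subject.subject_id,
    )


def cohort_feature_tables(subjects, seed=0, window=5, n_levels=32,
                          max_voxels=3600, progression_fraction=0.3):
    """Per-subject labeled feature tables with seeded voxel sampling."""
    tables = []
    for i, s in enumerate(subjects):
        rng = np.random.default_rng([seed, 7919, i])
        tables.append(
            subject_feature_table(
                s, window=window, n_levels=n_levels, max_voxels=max_voxels,
                rng=rng, progression_fraction=progression_fraction,
            )
        )
    return tables


def run_parameter_recovery(
    seed: int = 0,
    n_train: int = 10,
    n_heldout: int = 4,
    n_repeats: int = 3,
    strong: bool = True,
    max_voxels: int = 3600,
    max_iter: int = 250,
) -> dict:
    """Held-out voxel accuracy of the classifier on a seeded phantom cohort.

    Generates ``n_train + n_heldout`` subjects (strong default effects or
    the zero-shift null), extracts sampled peritumoral feature tables,
    then per repeat re-splits 70/15/15, re-trains the network and scores
    the pooled held-out voxels.  Returns the per-repeat accuracies, the
    held-out majority-class rate, and the per-repeat validation report.
    """
    effect = default_effect_table() if strong else zero_effect_table()
    params = PhantomParams(
        effect_table=effect, n_subjects=n_train + n_heldout, seed=seed
    )
    cohort = generate_cohort(params)
    tables = cohort_feature_tables(cohort, seed=seed, max_voxels=max_voxels)
    train_table = pd.concat(tables[:n_train], ignore_index=True)
    heldout_tables = tables[n_train:]
    config = TrainConfig(max_iter=max_iter, seed=seed)
    report = external_validate(
        train_table, heldout_tables, config, n_repeats=n_repeats, seed=seed
    )
    held = pd.concat(heldout_tables, ignore_index=True)
    y = held["label"].to_numpy()
    majority = 100.0 * max(y.mean(), 1.0 - y.mean())
    accs = report.loc[report["repeat"] != "mean", "accuracy"].to_list()
    return {
        "heldout_accuracies": accs,
        "majority_rate": float(majority),
        "n_voxels_total": int(sum(len(t) for t in tables)),
        "n_heldout_voxels": int(len(held)),
        "report": report,
    }


def run_null_calibration(
    seed: int = 0,
    n_seeds: int = 10,
    n_subjects: int = 8,
    voxels_per_subject: int = 300,
    alpha: float = 0.05,
) -> dict:
    """Type-I rate of the 294-feature screen on zero-effect phantom cohorts.

    Runs ``n_seeds`` independent null cohorts on a reduced 32 mm grid and
    pools the per-seed fractions of features flagged at ``alpha``.
    """
    fractions = []
    for s in range(n_seeds):
        params = PhantomParams(
            grid_shape=(32, 32, 32),
            core_radius_mm=5.0,
            progression_extent_mm=5.0,
            core_offset_mm=3.0,
            effect_table=zero_effect_table(),
            n_subjects=n_subjects,
            seed=seed + 100 + s,
        )
        cohort = generate_cohort(params)
        tables = cohort_feature_tables(
            cohort, seed=seed + 100 + s, max_voxels=voxels_per_subject
        )
        prog, non = subject_feature_means(tables)
        screen = feature_screen(prog, non, alpha=alpha)
        fractions.append(float(screen["significant"].mean()))
    fractions = np.asarray(fractions)
    return {
        "fractions": fractions.tolist(),
        "mean_fraction": float(fractions.mean()),
        "n_tests_per_seed": 294,
        "alpha": alpha,
    }
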
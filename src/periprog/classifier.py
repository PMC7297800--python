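"""Voxel-wise progression classification: splits, metrics, maps, validation.

Ties the feature table to the network trainer: the 70/15/15 random split,
confusion-matrix metrics in percent, per-voxel probability heat maps over
the peritumoral mask, and the external-validation report (three repeats,
each with a re-trained network, plus the aggregate row).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import NetworkModel, TrainConfig, predict_proba, train_network
from .radiomics.registry import feature_registry
from .radiomics.table import voxelwise_feature_table

__all__ = [
    "SplitSpec",
    "random_split",
    "fit_from_table",
    "confusion_metrics",
    "probability_heatmap",
    "overlap_metrics",
    "external_validate",
]


@dataclass(frozen=True)
class SplitSpec:
    """Random train/validation/test partition fractions."""

    train: float = 0.70
    validation: float = 0.15
    test: float = 0.15
    seed: int = 0

    def __post_init__(self):
        fr = (self.train, self.validation, self.test)
        if any(f <= 0 for f in fr):
            raise ValueError("fractions must be positive")
        if not math.isclose(sum(fr), 1.0, abs_tol=1e-9):
            raise ValueError("fractions must sum to 1")


def random_split(n_rows: int, spec: SplitSpec = SplitSpec()):
    """Disjoint, exhaustive (train, validation, test) index arrays.

    Validation and test sizes are round(n * fraction); the remainder goes
    to training.  Deterministic given the spec seed.
    """
    if n_rows < 3:
        raise ValueError("need at least 3 rows to split")
    n_val = round(n_rows * spec.validation)
    n_test = round(n_rows * spec.test)
    perm = np.random.default_rng(spec.seed).permutation(n_rows)
    val = np.sort(perm[:n_val])
    test = np.sort(perm[n_val : n_val + n_test])
    train = np.sort(perm[n_val + n_test :])
    return train, val, test


def _feature_matrix(table: pd.DataFrame):
    names = feature_registry().names
    return table[names].to_numpy(dtype=np.float64)


def fit_from_table(
    table: pd.DataFrame,
    split_spec: SplitSpec = SplitSpec(),
    config: TrainConfig = None,
):
    """Split a labeled feature table 70/15/15 and train the network.

    Returns ``(model, indices)`` where ``indices`` is the (train,
    validation, test) row partition used.
    """
    if "label" not in table.columns:
        raise ValueError("feature table carries no label column")
    X = _feature_matrix(table)
    y = table["label"].to_numpy(dtype=np.float64)
    idx = random_split(len(table), split_spec)
    tr, va, te = idx
    model = train_network(X[tr], y[tr], X[va], y[va], config)
    model.trace["split_sizes"] = [int(len(tr)), int(len(va)), int(len(te))]
    return model, idx


def confusion_metrics(probs, labels, threshold: float = 0.5) -> dict:
    """Sensitivity, specificity, accuracy, PPV and NPV in percent.

    Ratios with a zero denominator are returned as NaN and listed under
    the ``undefined`` key.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    if probs.size == 0:
        raise ValueError("no voxels")
    pred = (probs >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))

    def ratio(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    out = {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
    }
    out["undefined"] = [
        k for k in ("sensitivity", "specificity", "accuracy", "ppv", "npv")
        if math.isnan(out[k])
    ]
    return out


def probability_heatmap(
    model: NetworkModel,
    volumes,
    peritumoral_mask,
    window: int = 5,
    n_levels: int = 32,
) -> np.ndarray:
    """Per-voxel progression-probability map over the peritumoral mask.

    Voxels outside the mask are 0; inside, the model probability in (0,1).
    """
    mask = np.asarray(peritumoral_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty peritumoral mask")
    table = voxelwise_feature_table(volumes, mask, window, n_levels)
    probs = predict_proba(model, _feature_matrix(table))
    out = np.zeros(mask.shape, dtype=np.float64)
    out[mask] = probs
    return out


def overlap_metrics(prob_maps, truth_masks, eval_masks, threshold: float = 0.5) -> dict:
    """Pooled PPV/NPV/accuracy of probability maps against truth masks.

    Overlaps each binarized map with the true progression mask over the
    evaluation support (the peritumoral mask), pooling voxels across
    subjects.
    """
    probs, labels = [], []
    for pm, tm, em in zip(prob_maps, truth_masks, eval_masks):
        em = np.asarray(em, dtype=bool)
        probs.append(np.asarray(pm)[em])
        labels.append(np.asarray(tm, dtype=bool)[em])
    return confusion_metrics(np.concatenate(probs), np.concatenate(labels), threshold)


def external_validate(
    train_table: pd.DataFrame,
    heldout_tables,
    config: TrainConfig = None,
    n_repeats: int = 3,
    threshold: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """External validation report: one row per repeat plus the mean row.

    Each repeat re-splits and re-trains the network with a new seed, then
    pools the held-out subjects' voxels for PPV, NPV and overall accuracy.
    Raises if any held-out subject also appears in the training table.
    """
    config = config or TrainConfig()
    if "subject" in train_table.columns:
        train_subjects = set(train_table["subject"])
        for t in heldout_tables:
            leaked = train_subjects & set(t["subject"])
            if leaked:
                raise ValueError(f"subject leakage between cohorts: {sorted(leaked)}")
    held = pd.concat(heldout_tables, ignore_index=True)
    Xh = _feature_matrix(held)
    yh = held["label"].to_numpy(dtype=np.float64)
    rows = []
    for rep in range(n_repeats):
        rep_cfg = TrainConfig(
            hidden_sizes=config.hidden_sizes,
            max_iter=config.max_iter,
            patience=config.patience,
            tol_grad=config.tol_grad,
            seed=seed + 1000 * rep + config.seed,
        )
        model, _ = fit_from_table(
            train_table, SplitSpec(seed=seed + 1000 * rep), rep_cfg
        )
        m = confusion_metrics(predict_proba(model, Xh), yh, threshold)
        rows.append(
            {
                "repeat": f"Test {rep + 1}",
                "ppv": m["ppv"],
                "npv": m["npv"],
                "accuracy": m["accuracy"],
            }
        )
    report = pd.DataFrame(rows)
    mean_row = {
        "repeat": "mean",
        "ppv": report["ppv"].mean(),
        "npv": report["npv"].mean(),
        "accuracy": report["accuracy"].mean(),
    }
    return pd.concat([report, pd.DataFrame([mean_row])], ignore_index=True)
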
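"""Group-level comparisons: ROI means, paired t-tests, feature screens.

Per-subject ROI means of each modality (or radiomics feature) are compared
between the progression region and the non-progression comparators with
classical paired t-tests on the per-subject differences, two-sided p from
Student's t with n-1 degrees of freedom.  The 294-feature screen reports
raw p-values by default; Benjamini-Hochberg correction is available but
off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .radiomics.registry import feature_registry

__all__ = [
    "PairedTestResult",
    "roi_means",
    "paired_ttest",
    "subject_feature_means",
    "feature_screen",
]


@dataclass(frozen=True)
class PairedTestResult:
    """Classical paired t-test on per-subject differences."""

    t: float
    p: float
    n_pairs: int
    mean_diff: float
    degenerate: bool = False  # zero-variance differences


def roi_means(maps: dict, roi_set, subject_id=None) -> pd.DataFrame:
    """Per-ROI arithmetic means of each named map.

    ``maps`` is ``{variable name: 3D array}`` (modality volumes or feature
    maps); ROIs come from the RoiSet in its standard order (CE,
    progression, the four bands, NAWM).  Empty ROIs
    are omitted with a warning row count reduction.
    """
    rows = []
    for roi_label, mask in roi_set.labeled_rois():
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            import warnings

            warnings.warn(f"ROI {roi_label} is empty; omitted", stacklevel=2)
            continue
        for var, vol in maps.items():
            rows.append(
                {
                    "subject": subject_id,
                    "roi": roi_label,
                    "variable": var,
                    "mean": float(np.asarray(vol)[mask].mean()),
                }
            )
    return pd.DataFrame(rows)


def paired_ttest(x_per_subject, y_per_subject) -> PairedTestResult:
    """Paired t-test of two per-subject measurement vectors.

    Zero-variance differences are flagged: t = 0, p = 1 when the
    differences are identically zero, otherwise t = +/-inf, p = 0.
    """
    x = np.asarray(x_per_subject, dtype=float)
    y = np.asarray(y_per_subject, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need two equal-length 1D vectors")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite measurements")
    d = x - y
    mean_d = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        if mean_d == 0.0:
            return PairedTestResult(0.0, 1.0, n, 0.0, degenerate=True)
        t = np.inf if mean_d > 0 else -np.inf
        return PairedTestResult(float(t), 0.0, n, float(mean_d), degenerate=True)
    t = mean_d / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return PairedTestResult(float(t), float(p), n, float(mean_d))


def subject_feature_means(tables) -> tuple:
    """Per-subject ROI means of every feature from labeled feature tables.

    ``tables`` is an iterable of per-subject feature tables (the output of
    :func:`periprog.radiomics.voxelwise_feature_table` with labels).
    Returns ``(progression_means, nonprogression_means)`` as DataFrames
    indexed by subject with one column per feature.
    """
    names = feature_registry().names
    prog_rows, non_rows, index = [], [], []
    for t in tables:
        sid = t["subject"].iloc[0] if "subject" in t.columns else len(index)
        lab = t["label"].to_numpy()
        if not (lab == 1).any() or not (lab == 0).any():
            raise ValueError(f"subject {sid} lacks one of the two classes")
        prog_rows.append(t.loc[lab == 1, names].mean().to_numpy())
        non_rows.append(t.loc[lab == 0, names].mean().to_numpy())
        index.append(sid)
    prog = pd.DataFrame(prog_rows, index=index, columns=names)
    non = pd.DataFrame(non_rows, index=index, columns=names)
    return prog, non


def feature_screen(
    progression_means: pd.DataFrame,
    nonprogression_means: pd.DataFrame,
    alpha: float = 0.05,
    correction: str = None,
) -> pd.DataFrame:
    """Paired-t screen of all features, progression vs pooled non-progression.

    One paired t-test per feature across subjects; returns a tidy frame
    with t, raw two-sided p, the family (first_order vs second_order) and
    a ``significant`` flag at ``alpha``.  ``correction="bh"`` applies
    Benjamini-Hochberg to the p-values before thresholding (off by
    default; the screen is exploratory and reports raw p-values).
    """
    if not progression_means.columns.equals(nonprogression_means.columns):
        raise ValueError("mismatched feature columns")
    if len(progression_means) < 2:
        raise ValueError("need at least 2 subjects")
    reg = feature_registry()
    family = {
        f.name: ("first_order" if f.family == "first_order" else "second_order")
        for f in reg.features
    }
    rows = []
    for name in progression_means.columns:
        res = paired_ttest(
            progression_means[name].to_numpy(), nonprogression_means[name].to_numpy()
        )
        rows.append(
            {
                "feature": name,
                "family": family.get(name, "unknown"),
                "t": res.t,
                "p": res.p,
                "degenerate": res.degenerate,
            }
        )
    out = pd.DataFrame(rows)
    pvals = out["p"].to_numpy()
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        out["p_adjusted"] = p_adj
        out["significant"] = p_adj < alpha
    elif correction is None:
        out["significant"] = pvals < alpha
    else:
        raise ValueError("correction must be None or 'bh'")
    return out
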
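#!/usr/bin/env python
"""Screen all 294 features for progression vs non-progression differences.

On a strong-effect cohort, runs the paired-t screen of every feature
(progression ROI mean vs pooled non-progression mean per subject), reports
the significant counts by family (first order vs second order) and then
checks the type-I calibration of the same screen on zero-effect cohorts.
"""

from pathlib import Path

from periprog.experiments import (
    cohort_feature_tables,
    run_null_calibration,
)
from periprog.phantom import PhantomParams, generate_cohort
from periprog.stats import feature_screen, subject_feature_means

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    params = PhantomParams(n_subjects=8, seed=2024)
    cohort = generate_cohort(params)
    tables = cohort_feature_tables(cohort, seed=2024, max_voxels=1500)
    prog, non = subject_feature_means(tables)
    screen = feature_screen(prog, non, alpha=0.05)
    RESULTS.mkdir(exist_ok=True)
    screen.to_csv(RESULTS / "feature_screen.csv", index=False)
    by_family = screen.groupby("family")["significant"].agg(["sum", "count"])
    for fam, row in by_family.iterrows():
        print(f"{int(row['sum'])}/{int(row['count'])} {fam} features "
              "significant at p < 0.05")
    by_mod = screen.assign(
        modality=screen["feature"].str.split(".").str[0]
    ).groupby("modality")["significant"].mean()
    print("\nflag rate by modality (DTI-q should sit near the 5% floor):")
    print(by_mod.to_string(float_format=lambda x: f"{x:.2f}"))

    cal = run_null_calibration(seed=2024, n_seeds=10)
    print(f"\nnull-cohort type-I rate: {100 * cal['mean_fraction']:.1f}% "
          f"of features flagged at alpha = 5% (10 seeds)")


if __name__ == "__main__":
    main()
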
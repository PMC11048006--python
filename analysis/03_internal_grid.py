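#!/usr/bin/env python
"""Internal validation: the cohort x region x classifier experiment grid.

Loads the per-region feature tables written by 02_extract_features.py (plus
the pooled cohort), runs the stratified 67/33 split once per cohort, applies
the leakage-safe preparation chain per region (z-score -> correlation filter
at |r| > 0.8 -> gradient-boosted importance top-k -> SMOTE on the training
rows), fits the classifier zoo, and ranks regions and classifiers by average
test AUC.

Writes: results/internal_auc_table.csv, results/region_ranking.csv,
        results/classifier_ranking.csv
"""

import warnings
from pathlib import Path

import pandas as pd

from subgrade.models import PrepConfig, SplitSpec, run_grid, scaled_down_specs

RESULTS = Path(__file__).resolve().parent.parent / "results"
REGIONS = ("full", "core25", "core50", "core75", "periphery25", "periphery50", "periphery75")


def load_cohort_tables() -> dict[str, dict[str, pd.DataFrame]]:
    src = RESULTS / "features"
    cohorts: dict[str, dict[str, pd.DataFrame]] = {}
    for name in ("cohort1", "cohort2"):
        cohorts[name] = {
            region: pd.read_csv(src / f"{name}_{region}.csv", index_col="subject_id")
            for region in REGIONS
        }
    cohorts["combined"] = {
        region: pd.concat(
            [cohorts[c][region].rename(index=lambda s, c=c: f"{c}:{s}") for c in ("cohort1", "cohort2")]
        )
        for region in REGIONS
    }
    return cohorts


def main() -> None:
    warnings.filterwarnings("ignore")
    cohorts = load_cohort_tables()
    grid = run_grid(cohorts, scaled_down_specs(), SplitSpec(seed=42), PrepConfig(k_selected=30))
    grid.auc_table().to_csv(RESULTS / "internal_auc_table.csv", index=False)

    region_rows, classifier_rows = [], []
    for cohort in cohorts:
        regions = grid.region_average_auc(cohort)
        classifiers = grid.classifier_average_auc(cohort)
        print(f"\n{cohort}: best region {regions.index[0]} ({regions.iloc[0]:.1f}%),"
              f" best classifier {classifiers.index[0]} ({classifiers.iloc[0]:.1f}%)")
        for region, auc in regions.items():
            region_rows.append({"cohort": cohort, "region": region, "avg_auc": auc})
        for model, auc in classifiers.items():
            classifier_rows.append({"cohort": cohort, "model": model, "avg_auc": auc})
    pd.DataFrame(region_rows).to_csv(RESULTS / "region_ranking.csv", index=False)
    pd.DataFrame(classifier_rows).to_csv(RESULTS / "classifier_ranking.csv", index=False)
    print(f"\n{grid.n_cells} fitted cells; tables written to {RESULTS}")


if __name__ == "__main__":
    main()
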
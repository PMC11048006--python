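#!/usr/bin/env python
"""External validation: train on one cohort, score the other, both directions.

Everything fitted (scaler, correlation filter, importance selection, SMOTE,
models) sees only the training cohort; the test cohort is transformed and
scored.

Writes: results/external_auc_table.csv
"""

import warnings
from pathlib import Path

import pandas as pd

from subgrade.models import PrepConfig, external_validate, scaled_down_specs

RESULTS = Path(__file__).resolve().parent.parent / "results"
REGIONS = ("full", "core25", "core50", "core75", "periphery25", "periphery50", "periphery75")


def load(name: str) -> dict[str, pd.DataFrame]:
    src = RESULTS / "features"
    return {
        region: pd.read_csv(src / f"{name}_{region}.csv", index_col="subject_id")
        for region in REGIONS
    }


def main() -> None:
    warnings.filterwarnings("ignore")
    cohort1, cohort2 = load("cohort1"), load("cohort2")
    rows = []
    for train_name, train, test_name, test in (
        ("cohort1", cohort1, "cohort2", cohort2),
        ("cohort2", cohort2, "cohort1", cohort1),
    ):
        cells = external_validate(train, test, scaled_down_specs(), PrepConfig(k_selected=30))
        for (region, model), cell in cells.items():
            rows.append(
                {
                    "train": train_name,
                    "test": test_name,
                    "region": region,
                    "model": model,
                    "auc": cell.report.auc,
                }
            )
        best = max(cells.values(), key=lambda c: c.report.auc)
        print(
            f"train {train_name} -> test {test_name}: best {best.model} on "
            f"{best.region}, AUC {best.report.auc:.1f}%"
        )
    pd.DataFrame(rows).to_csv(RESULTS / "external_auc_table.csv", index=False)
    print(f"wrote external validation table to {RESULTS}")


if __name__ == "__main__":
    main()
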
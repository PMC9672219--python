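"""Recompute the published derivation-cohort summary arithmetic.

The clinical images are not shareable, but every published number that
depends only on published inputs can be reproduced: the median (± MAD)
aggregation of the per-fold cross-validation metrics, the
cohort-composition percentages, and the patient-flow accounting.  The
published F1 median and two published MAD values are inconsistent with
their own fold values and are reported here as recomputed.

Writes: results/cv_aggregates.csv, results/cohort_composition.csv
"""

from pathlib import Path

import pandas as pd

from topoliver.modeling import aggregate_folds, cohort_summary
from topoliver.reference_cohort import (
    DERIVATION_FOLD_METRICS,
    N_DERIVATION,
    N_EXCLUDED,
    N_FEMALES,
    N_IBD,
    N_REVIEWED,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    rows = []
    for metric, folds in DERIVATION_FOLD_METRICS.items():
        median, mad = aggregate_folds(folds)
        rows.append({"metric": metric, **{f"fold_{i+1}": v for i, v in enumerate(folds)},
                     "median": median, "mad": round(mad, 4)})
    agg = pd.DataFrame(rows)
    agg.to_csv(ROOT / "results" / "cv_aggregates.csv", index=False)
    print("derivation-cohort fold aggregation (median ± MAD):")
    print(agg[["metric", "median", "mad"]].to_string(index=False))

    table = pd.DataFrame(
        {
            "female": [1] * N_FEMALES + [0] * (N_DERIVATION - N_FEMALES),
            "ibd": [1] * N_IBD + [0] * (N_DERIVATION - N_IBD),
        }
    )
    comp = cohort_summary(table, categorical=["female", "ibd"])
    comp.to_csv(ROOT / "results" / "cohort_composition.csv", index=False)
    print("\nderivation-cohort composition:")
    print(comp[["variable", "summary"]].to_string(index=False))

    print(
        f"\npatient flow: {N_REVIEWED} reviewed - {N_EXCLUDED} excluded "
        f"= {N_REVIEWED - N_EXCLUDED} potentially eligible"
    )


if __name__ == "__main__":
    main()
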
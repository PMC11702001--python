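#!/usr/bin/env python
"""Endpoint outcomes by gain status: the adjusted-difference model.

Fits the maximum-likelihood random-intercept model of endpoint LSAS on
time (post-intervention, 3-month follow-up), sudden-gain status, their
interaction and baseline LSAS, then reports the covariate-adjusted
group difference at each timepoint with raw-scale Cohen's d, alongside
the unadjusted cell means and SDs.  Writes results/outcome_model.csv.
"""

from pathlib import Path

import pandas as pd

import suddengain as sg
from suddengain.pipeline import endpoint_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = sg.read_cohort(ROOT / "cohort" / "cohort.csv", format="long",
                            endpoints_path=ROOT / "cohort" / "endpoints.csv")
    included, _, _ = sg.apply_inclusion_filter(cohort, 8)
    gains = pd.read_csv(ROOT / "gains.csv")

    endpoints = endpoint_table(included, gains)
    result = sg.fit_outcome_model(endpoints)

    print("unadjusted cells (mean, SD):")
    print(result.cell_stats.round(2).to_string(index=False))
    print("\nadjusted group differences (no-gain minus gain):")
    print(result.differences.round(3).to_string(index=False))

    cells = result.cell_stats.copy()
    cells["kind"] = "cell"
    diffs = result.differences.copy()
    diffs["kind"] = "adjusted_difference"
    pd.concat([cells, diffs], ignore_index=True).to_csv(
        ROOT / "outcome_model.csv", index=False)
    print(f"\nwritten to {ROOT}/outcome_model.csv")


if __name__ == "__main__":
    main()
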
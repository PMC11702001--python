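#!/usr/bin/env python
"""Process measures around the gain: consecutive mixed-model contrasts.

Aligns every measure to each participant's primary gain (offsets
n-2..n+3), fits a random-intercept model per measure with timepoint as
a 6-level factor, and tabulates the five consecutive contrasts with
Bonferroni-adjusted p-values and raw-scale effect sizes.  The question
is timing: which processes move before the symptom drop and which move
with it.  Writes results/around_gain.csv and results/contrasts.csv.
"""

from pathlib import Path

import pandas as pd

import suddengain as sg

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = sg.read_cohort(ROOT / "cohort" / "cohort.csv", format="long")
    included, _, _ = sg.apply_inclusion_filter(cohort, 8)
    gains = pd.read_csv(ROOT / "gains.csv")
    primaries = gains[gains["is_primary"]]

    around = sg.extract_window(included, primaries, sg.PROCESS_MEASURES)
    around.to_csv(ROOT / "around_gain.csv", index=False)

    table = sg.contrast_table(around, sg.PROCESS_MEASURES)
    table.to_csv(ROOT / "contrasts.csv", index=False)
    print(table.round(3).to_string(index=False))

    sig = table[table["p_adj"] < 0.05]
    print("\nBonferroni-significant contrasts:")
    for _, row in sig.iterrows():
        print(f"  {row['measure']:>14} {row['contrast']}: "
              f"{row['estimate']:+.2f} (d={row['d']:.2f})")
    print(f"\nwritten to {ROOT}/contrasts.csv")


if __name__ == "__main__":
    main()
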
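#!/usr/bin/env python
"""Render the report figures from the detection and alignment outputs.

Four panels: mean LSAS across the six around-gain timepoints, the
pre-gain-week histogram, mean weekly trajectories by gain status
(clipped at week 14, the median end of treatment), and the process-
measure panel.  Written under results/figures/.
"""

from pathlib import Path

import pandas as pd

import suddengain as sg
from suddengain.pipeline import RunConfig, make_figures

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = sg.read_cohort(ROOT / "cohort" / "cohort.csv", format="long")
    included, _, _ = sg.apply_inclusion_filter(cohort, 8)
    gains = pd.read_csv(ROOT / "gains.csv")
    around = pd.read_csv(ROOT / "around_gain.csv")

    fig_dir = ROOT / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    make_figures(included, gains, around, fig_dir,
                 RunConfig(out_dir=ROOT, seed=sg.FIXTURE_SEED))
    for png in sorted(fig_dir.glob("*.png")):
        print(f"wrote {png}")


if __name__ == "__main__":
    main()
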
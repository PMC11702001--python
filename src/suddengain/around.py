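"""Align measures to each participant's primary gain (offsets n-2..n+3).

The process analysis asks how cognitions, attention and mood move in the
weeks surrounding a sudden gain.  Each participant with a primary gain
at pre-gain week n contributes one row per measure per offset label
(n-2, n-1, n, n+1, n+2, n+3), valued at the corresponding *absolute*
week of their own trajectory.  Offsets falling before week 1 or beyond
the participant's last week, or landing on an unobserved week, are
emitted as missing — never interpolated, never shifted to the nearest
observation.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .measures import PROCESS_MEASURES
from .trajectory import Cohort

#: Offset labels in timeline order.
TIMEPOINTS = ("n-2", "n-1", "n", "n+1", "n+2", "n+3")
_OFFSETS = (-2, -1, 0, 1, 2, 3)


def extract_window(
    cohort: Cohort,
    primary_gains: pd.DataFrame,
    measures: Iterable[str] = PROCESS_MEASURES,
) -> pd.DataFrame:
    """Long around-gain table: participant_id, measure, timepoint, value.

    ``primary_gains`` needs columns ``participant_id`` and ``n`` with one
    row per participant (the output of primary-gain selection).  Missing
    offsets appear as NaN rows so the table always spans all six labels.
    """
    measures = list(measures)
    if primary_gains.duplicated("participant_id").any():
        raise ValueError("expected one primary gain per participant")
    known = set(cohort.participants)
    rows = []
    for _, gain in primary_gains.sort_values("participant_id").iterrows():
        pid, n = str(gain["participant_id"]), int(gain["n"])
        if pid not in known:
            raise ValueError(f"participant {pid!r} has a gain but no trajectory")
        n_weeks = cohort.n_weeks(pid)
        for measure in measures:
            series = cohort.series(pid, measure)
            for label, off in zip(TIMEPOINTS, _OFFSETS):
                week = n + off
                value = series.get(week, np.nan) if 1 <= week <= n_weeks else np.nan
                rows.append(
                    {"participant_id": pid, "measure": measure,
                     "timepoint": label, "value": value}
                )
    return pd.DataFrame(rows, columns=["participant_id", "measure", "timepoint", "value"])
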
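"""Sudden-gain detection on weekly LSAS trajectories.

A sudden gain is a large symptom improvement between two consecutive
treatment weeks n ("pre-gain") and n+1 ("post-gain") that jointly
satisfies three criteria:

1. absolute magnitude: the drop is at least ``cutoff`` LSAS points
   (default 12, a reliable-change-index-based cutoff for the scale);
2. relative magnitude: the drop is at least ``pct`` (default 25%) of the
   pre-gain score;
3. stability: the mean of the up-to-three pre-gain scores exceeds the
   mean of the up-to-three post-gain scores by strictly more than a
   critical multiple of their pooled standard deviation.

With fully observed windows the criterion-3 multiplier is the familiar
2.78; when one value of a window is missing the comparison rests on
fewer observations, so the multiplier is raised to the corresponding
two-sided 95% Student-t quantile (df = n_pre + n_post - 2): 2.776 for
(3,3), 3.182 for (2,3)/(3,2) and 4.303 for (2,2).  No imputation is ever
performed; an interval whose endpoint week is unobserved, or whose
windows retain fewer than ``min_window`` values, is simply not a
candidate.

A gain is *reversed* if any later score climbs back to the post-gain
score plus half the magnitude or more.  When a participant has several
gains, the *primary* gain is the largest (ties to the earliest), and
only that one enters the group-level analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .measures import LSAS
from .trajectory import Cohort


@dataclass(frozen=True)
class GainCriteria:
    """Parameters of the three-criteria definition."""

    cutoff: float = 12.0            # criterion 1: minimum absolute LSAS drop
    pct: float = 0.25               # criterion 2: minimum fraction of pre-gain score
    stability_alpha: float = 0.05   # criterion 3: two-sided tail probability
    min_window: int = 2             # minimum observed values per window

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not 0 < self.pct < 1:
            raise ValueError("pct must be in (0, 1)")
        if not 0 < self.stability_alpha < 1:
            raise ValueError("stability_alpha must be in (0, 1)")
        if self.min_window not in (2, 3):
            raise ValueError("min_window must be 2 or 3")


@dataclass(frozen=True)
class GainWindow:
    """Candidate interval (n, n+1) with its flanking observations."""

    n: int
    pre_values: tuple[float, ...]    # observed values among weeks n-2, n-1, n
    post_values: tuple[float, ...]   # observed values among weeks n+1, n+2, n+3

    @property
    def score_n(self) -> float:
        return self.pre_values[-1]

    @property
    def score_n1(self) -> float:
        return self.post_values[0]


@dataclass(frozen=True)
class SuddenGain:
    participant_id: str
    n: int
    score_n: float
    score_n1: float
    magnitude: float
    reversed: bool = False
    reversal_week: int | None = None


@dataclass
class CohortGainSummary:
    n_participants: int
    n_with_gain: int
    occurrence_rate_pct: int
    n_gains_total: int
    gains_per_participant: dict[int, int]
    magnitude_mean: float | None
    magnitude_sd: float | None
    n_reversals: int
    pre_gain_week_histogram: dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "n_with_gain": self.n_with_gain,
            "occurrence_rate_pct": self.occurrence_rate_pct,
            "n_gains_total": self.n_gains_total,
            "gains_per_participant": {str(k): v for k, v in sorted(self.gains_per_participant.items())},
            "magnitude_mean": self.magnitude_mean,
            "magnitude_sd": self.magnitude_sd,
            "n_reversals": self.n_reversals,
            "pre_gain_week_histogram": {str(k): v for k, v in sorted(self.pre_gain_week_histogram.items())},
        }


# -- criteria --------------------------------------------------------------

def check_criterion1(score_n: float, score_n1: float, cutoff: float = 12.0) -> bool:
    """Absolute drop of at least ``cutoff`` points (inclusive)."""
    if score_n is None or score_n1 is None:
        raise ValueError("criterion 1 requires both scores observed")
    return bool((score_n - score_n1) >= cutoff)


def check_criterion2(score_n: float, score_n1: float, pct: float = 0.25) -> bool:
    """Drop of at least ``pct`` of the pre-gain score (inclusive).

    A pre-gain score of zero admits no positive drop, so returns False.
    """
    if score_n <= 0:
        return False
    return bool((score_n - score_n1) >= pct * score_n)


def critical_value(n_pre: int, n_post: int, stability_alpha: float = 0.05) -> float:
    """Criterion-3 multiplier for windows with n_pre/n_post observations.

    The two-sided Student-t quantile at 1 - alpha/2 with
    df = n_pre + n_post - 2.  For full (3, 3) windows this is 2.776
    (printed as 2.78); dropping observations raises it (3.182, 4.303),
    i.e. the stability test becomes more stringent with missing data.
    """
    if n_pre < 2 or n_post < 2:
        raise ValueError("criterion 3 needs at least 2 observations per window")
    if n_pre > 3 or n_post > 3:
        raise ValueError("windows hold at most 3 observations")
    df = n_pre + n_post - 2
    return float(stats.t.ppf(1 - stability_alpha / 2, df))


def check_criterion3(window: GainWindow, criteria: GainCriteria = GainCriteria()) -> bool:
    """Mean pre-post difference strictly exceeds critical x pooled SD.

    Pooled SD = sqrt((sd_pre^2 + sd_post^2) / 2) using sample (n-1) SDs.
    With zero variance in both windows any positive mean difference
    passes (the trajectory is perfectly stable on both sides).
    """
    pre = np.asarray(window.pre_values, dtype=float)
    post = np.asarray(window.post_values, dtype=float)
    crit = critical_value(len(pre), len(post), criteria.stability_alpha)
    pooled_sd = math.sqrt((pre.std(ddof=1) ** 2 + post.std(ddof=1) ** 2) / 2)
    return bool((pre.mean() - post.mean()) > crit * pooled_sd)


# -- candidate enumeration and detection -----------------------------------

def enumerate_candidates(
    series: Mapping[int, float],
    criteria: GainCriteria = GainCriteria(),
    n_weeks: int | None = None,
) -> list[GainWindow]:
    """All intervals (n, n+1) eligible for the three-criteria test.

    ``series`` maps week -> observed LSAS value.  Both endpoint weeks
    must be observed, and each window must retain at least
    ``criteria.min_window`` values among the slots that exist within
    weeks 1..n_weeks (slots beyond the trajectory edges do not exist;
    slots inside that are unobserved count as missing).
    """
    if not series:
        return []
    if n_weeks is None:
        n_weeks = max(series)
    out: list[GainWindow] = []
    for n in range(1, n_weeks):
        if n not in series or (n + 1) not in series:
            continue
        pre = tuple(series[w] for w in (n - 2, n - 1, n) if w >= 1 and w in series)
        post = tuple(series[w] for w in (n + 1, n + 2, n + 3) if w <= n_weeks and w in series)
        if len(pre) >= criteria.min_window and len(post) >= criteria.min_window:
            out.append(GainWindow(n=n, pre_values=pre, post_values=post))
    return out


def detect_reversal(
    score_n1: float, magnitude: float, subsequent: Mapping[int, float]
) -> tuple[bool, int | None]:
    """First later week at which half the gain (or more) is lost.

    ``subsequent`` holds observed values at weeks strictly after n+1.
    The threshold is inclusive: for a 60 -> 40 gain a later score of 50
    already counts as a reversal.
    """
    threshold = score_n1 + 0.5 * magnitude
    for week in sorted(subsequent):
        if subsequent[week] >= threshold:
            return True, week
    return False, None


def detect_gains(
    series: Mapping[int, float],
    criteria: GainCriteria = GainCriteria(),
    participant_id: str = "",
    n_weeks: int | None = None,
) -> list[SuddenGain]:
    """All sudden gains in one trajectory, ordered by pre-gain week."""
    gains: list[SuddenGain] = []
    for window in enumerate_candidates(series, criteria, n_weeks=n_weeks):
        s_n, s_n1 = window.score_n, window.score_n1
        if not check_criterion1(s_n, s_n1, criteria.cutoff):
            continue
        if not check_criterion2(s_n, s_n1, criteria.pct):
            continue
        if not check_criterion3(window, criteria):
            continue
        magnitude = s_n - s_n1
        subsequent = {w: v for w, v in series.items() if w > window.n + 1}
        rev, rev_week = detect_reversal(s_n1, magnitude, subsequent)
        gains.append(
            SuddenGain(
                participant_id=participant_id,
                n=window.n,
                score_n=s_n,
                score_n1=s_n1,
                magnitude=magnitude,
                reversed=rev,
                reversal_week=rev_week,
            )
        )
    return sorted(gains, key=lambda g: g.n)


def select_primary_gain(gains: Sequence[SuddenGain]) -> SuddenGain | None:
    """Largest-magnitude gain; ties broken by the earliest pre-gain week."""
    if not gains:
        return None
    pids = {g.participant_id for g in gains}
    if len(pids) > 1:
        raise ValueError("primary-gain selection is per participant")
    return min(gains, key=lambda g: (-g.magnitude, g.n))


def detect_cohort(
    cohort: Cohort, criteria: GainCriteria = GainCriteria()
) -> pd.DataFrame:
    """Run detection for every participant; tidy gains table.

    Columns: participant_id, n, score_n, score_n1, magnitude, reversed,
    reversal_week, is_primary.  Participants without gains contribute no
    rows.
    """
    rows = []
    for pid in cohort.participants:
        series = cohort.series(pid, LSAS)
        gains = detect_gains(series, criteria, participant_id=pid,
                             n_weeks=cohort.n_weeks(pid))
        primary = select_primary_gain(gains)
        for g in gains:
            rows.append(
                {
                    "participant_id": g.participant_id,
                    "n": g.n,
                    "score_n": g.score_n,
                    "score_n1": g.score_n1,
                    "magnitude": g.magnitude,
                    "reversed": g.reversed,
                    "reversal_week": g.reversal_week,
                    "is_primary": g is primary,
                }
            )
    columns = ["participant_id", "n", "score_n", "score_n1", "magnitude",
               "reversed", "reversal_week", "is_primary"]
    return pd.DataFrame(rows, columns=columns)


# -- cohort summaries ------------------------------------------------------

def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def summarize_cohort(gains: pd.DataFrame, cohort: Cohort) -> CohortGainSummary:
    """Cohort-level gain statistics over ALL detected gains.

    The occurrence rate is the percentage of participants with at least
    one gain, rounded half away from zero; magnitude statistics and the
    pre-gain-week histogram pool every gain, not only primaries.
    """
    n_participants = cohort.n_participants
    if gains.empty:
        return CohortGainSummary(
            n_participants=n_participants, n_with_gain=0, occurrence_rate_pct=0,
            n_gains_total=0, gains_per_participant={}, magnitude_mean=None,
            magnitude_sd=None, n_reversals=0, pre_gain_week_histogram={},
        )
    per = gains.groupby("participant_id").size()
    counts = per.value_counts().to_dict()
    mags = gains["magnitude"].astype(float)
    rate = 100.0 * len(per) / n_participants if n_participants else 0.0
    hist = gains["n"].value_counts().sort_index().to_dict()
    return CohortGainSummary(
        n_participants=n_participants,
        n_with_gain=int(len(per)),
        occurrence_rate_pct=_round_half_away(rate),
        n_gains_total=int(len(gains)),
        gains_per_participant={int(k): int(v) for k, v in counts.items()},
        magnitude_mean=float(mags.mean()),
        magnitude_sd=float(mags.std(ddof=1)) if len(mags) > 1 else None,
        n_reversals=int(gains["reversed"].sum()),
        pre_gain_week_histogram={int(k): int(v) for k, v in hist.items()},
    )


def compare_duration(
    sg_weeks: Iterable[float], nosg_weeks: Iterable[float]
) -> dict:
    """Mann-Whitney U comparison of treatment duration between groups.

    Guards against a spurious dose-response reading of the occurrence
    rate: if gains simply reflected longer treatment, the gain group
    would show more weeks.  Two-sided, tie-corrected; U is reported for
    the gain group.
    """
    sg = np.asarray(list(sg_weeks), dtype=float)
    nosg = np.asarray(list(nosg_weeks), dtype=float)
    if sg.size == 0:
        raise ValueError("gain group is empty")
    if nosg.size == 0:
        raise ValueError("no-gain group is empty")
    res = stats.mannwhitneyu(sg, nosg, alternative="two-sided")
    return {
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "mean_sg": float(sg.mean()),
        "mean_nosg": float(nosg.mean()),
        "n_sg": int(sg.size),
        "n_nosg": int(nosg.size),
    }
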
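"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates 8-30-week LSAS trajectories from a guided
internet-based cognitive-therapy cohort: a high, noisy baseline, a
gradual linear improvement, AR(1)-correlated week-to-week fluctuation,
and — for the gain group — one or two injected persistent step drops.
Process measures (negative-cognition frequency and belief, two
self-focused-attention items, PHQ-9 mood) are generated with drops
timed relative to the gain: cognition frequency begins to fall one
interval before the gain, belief and attention fall at the gain
interval, and mood drifts without any gain-locked change.

Every simulated participant is *certified*: the realised (noisy,
integer-rounded, missingness-applied) LSAS series is scanned by a
self-contained brute-force interval checker, and the set of qualifying
sudden-gain intervals must equal exactly the set of injected ones.
Trajectories that fail (an injected gain drowned by noise, or a
spurious qualifying interval) are resampled, so ground truth is exact
by construction: the detector owes the cohort 100% sensitivity and
zero false positives, and any discrepancy is a detector bug.

Calibration targets (cohort descriptives the defaults reproduce):
occurrence ~39% of participants with >=1 gain, ~23% of gainers with a
second gain, baseline LSAS ~N(85.7, 21.4) / N(80.1, 18.9) for the
gain / no-gain groups, certified gain magnitudes with mean ~25.3 and
SD ~11.3, treatment length ~N(14.5, 3.3) within 8-30 weeks, and
pre-gain weeks concentrated at weeks 2 and 6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .detection import GainCriteria
from .measures import (
    LSAS, PHQ9, SCQ_BELIEF, SCQ_FREQUENCY, SFA_DIFFICULT, SFA_GENERAL,
    MeasureSpec, default_registry,
)
from .trajectory import Cohort

#: Documented seed of the packaged replication fixture.
FIXTURE_SEED = 788


class SimulationError(RuntimeError):
    """Raised when certification fails after the bounded retry budget."""


@dataclass(frozen=True)
class ProcessSpec:
    """Generation parameters for one process measure.

    ``drops`` lists (shift, amount) pairs: the measure falls by
    ``amount`` from week n + shift onwards, where n is the pre-gain
    week of the participant's primary gain.  shift=0 places the drop on
    the interval (n-1 -> n), i.e. *before* the symptom gain; shift=1
    places it on the gain interval itself.
    """

    level: float
    slope: float            # gradual improvement per week (subtracted)
    between_sd: float       # participant random-intercept SD
    resid_sd: float         # within-participant residual SD
    drops: tuple[tuple[int, float], ...] = ()


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_participants: int = 146
    gain_prevalence: float = 0.39          # P(participant has >= 1 gain)
    p_second_gain: float = 13 / 57         # P(second gain | >= 1 gain)

    baseline_mean_sg: float = 85.74
    baseline_sd_sg: float = 21.35
    baseline_mean_nosg: float = 80.12
    baseline_sd_nosg: float = 18.88
    baseline_bounds: tuple[float, float] = (35.0, 140.0)

    # Raw step-magnitude distribution: a shifted gamma with a hard
    # floor, matching the shape qualifying gains must have (nothing
    # below the absolute cutoff, a right skew above it).  The raw mean
    # sits slightly below the target because the realised interval drop
    # adds the week's gradual improvement; the certified drops then
    # average ~25.3 with SD ~11.3.
    magnitude_mean: float = 19.8
    magnitude_sd: float = 12.5
    magnitude_min: float = 9.0

    duration_mean: float = 14.53
    duration_sd: float = 3.33
    duration_range: tuple[int, int] = (8, 30)

    slope_sg: float = 3.0                  # LSAS points of gradual gain per week
    slope_nosg: float = 2.1
    ar_coef: float = 0.3
    innovation_sd: float = 2.5
    missing_rate: float = 0.08
    min_observed_lsas: int = 8

    #: weights over candidate pre-gain weeks (renormalised per duration)
    pre_gain_week_weights: tuple[tuple[int, float], ...] = (
        (2, 0.30), (3, 0.08), (4, 0.08), (5, 0.10), (6, 0.22),
        (7, 0.06), (8, 0.05), (9, 0.04), (10, 0.03), (11, 0.02), (12, 0.02),
    )

    reversal_rate: float = 0.0             # reversals were rare; off by default
    followup_extra_drop_sg: float = 4.0    # LSAS change from post to 3-month FU
    followup_extra_drop_nosg: float = 10.5
    followup_noise_sd: float = 8.0

    process: Mapping[str, ProcessSpec] = field(default_factory=lambda: {
        SCQ_FREQUENCY: ProcessSpec(level=78.0, slope=0.5, between_sd=5.0,
                                   resid_sd=6.0, drops=((0, 5.81), (1, 8.64))),
        SCQ_BELIEF: ProcessSpec(level=1400.0, slope=12.0, between_sd=120.0,
                                resid_sd=160.0, drops=((1, 194.65),)),
        SFA_GENERAL: ProcessSpec(level=5.5, slope=0.06, between_sd=0.7,
                                 resid_sd=0.8, drops=((1, 0.83),)),
        SFA_DIFFICULT: ProcessSpec(level=6.0, slope=0.05, between_sd=0.7,
                                   resid_sd=0.9, drops=((1, 0.86),)),
        PHQ9: ProcessSpec(level=12.0, slope=0.15, between_sd=4.0,
                          resid_sd=2.2, drops=()),
    })

    max_attempts: int = 1000
    criteria: GainCriteria = field(default_factory=GainCriteria)

    def pct_feasibility(self, expected_score: float, magnitude: float,
                        slope: float, sd_diff: float) -> bool:
        """Can a gain of this magnitude satisfy the relative-drop rule here?"""
        attainable = magnitude + slope + sd_diff
        return attainable >= self.criteria.pct * expected_score

    def validate(self) -> None:
        for p in (self.gain_prevalence, self.p_second_gain, self.missing_rate):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        lo, hi = self.duration_range
        if not (8 <= lo <= hi <= 30):
            raise ValueError("duration_range must lie within [8, 30]")
        for v in (self.baseline_sd_sg, self.baseline_sd_nosg, self.magnitude_sd,
                  self.duration_sd, self.innovation_sd):
            if v < 0:
                raise ValueError("scale parameters must be non-negative")
        if not -1 < self.ar_coef < 1:
            raise ValueError("ar_coef must be in (-1, 1) for stationarity")


@dataclass
class SimCohort:
    """A generated cohort plus its exact injected ground truth."""

    cohort: Cohort
    truth: pd.DataFrame     # participant_id, n, magnitude (injected), realized_magnitude, reversed
    config: SimConfig

    @property
    def gain_participants(self) -> list[str]:
        return sorted(self.truth["participant_id"].unique().tolist())


# -- low-level pieces ------------------------------------------------------

def ar1_noise(rng: np.random.Generator, length: int, rho: float, innovation_sd: float) -> np.ndarray:
    """Stationary AR(1) series of the given length."""
    e = np.empty(length)
    if innovation_sd == 0:
        e.fill(0.0)
        return e
    e[0] = rng.normal(0.0, innovation_sd / math.sqrt(1.0 - rho**2))
    for t in range(1, length):
        e[t] = rho * e[t - 1] + rng.normal(0.0, innovation_sd)
    return e


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float = math.inf) -> float:
    if sd == 0:
        return float(min(max(mean, lo), hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise SimulationError(f"truncated normal ({mean}, {sd}) on [{lo}, {hi}] rejected 1000 draws")


def _draw_magnitude(rng: np.random.Generator, config: SimConfig,
                    floor: float) -> float:
    """Step magnitude: ``floor + Gamma`` with the configured mean and SD."""
    lo = max(config.magnitude_min, floor)
    excess = config.magnitude_mean - lo
    if excess < 1.0 or config.magnitude_sd <= 0:
        return lo + rng.exponential(max(excess, 1.0))
    shape = (excess / config.magnitude_sd) ** 2
    scale = config.magnitude_sd**2 / excess
    return float(lo + rng.gamma(shape, scale))


def _qualifying_intervals(series: Mapping[int, float], n_weeks: int,
                          criteria: GainCriteria) -> list[int]:
    """Self-contained brute-force scan used for certification.

    Deliberately re-derives the three criteria from their definitions
    (plain python arithmetic, scipy t quantile) rather than calling the
    detection module, so certification and detection stay independent.
    """
    hits = []
    for n in range(1, n_weeks):
        if n not in series or (n + 1) not in series:
            continue
        pre = [series[w] for w in (n - 2, n - 1, n) if 1 <= w <= n_weeks and w in series]
        post = [series[w] for w in (n + 1, n + 2, n + 3) if 1 <= w <= n_weeks and w in series]
        if len(pre) < criteria.min_window or len(post) < criteria.min_window:
            continue
        drop = series[n] - series[n + 1]
        if drop < criteria.cutoff:
            continue
        if series[n] <= 0 or drop < criteria.pct * series[n]:
            continue
        mean_pre = sum(pre) / len(pre)
        mean_post = sum(post) / len(post)
        var_pre = sum((x - mean_pre) ** 2 for x in pre) / (len(pre) - 1)
        var_post = sum((x - mean_post) ** 2 for x in post) / (len(post) - 1)
        tcrit = float(stats.t.ppf(1 - criteria.stability_alpha / 2,
                                  len(pre) + len(post) - 2))
        if (mean_pre - mean_post) > tcrit * math.sqrt((var_pre + var_post) / 2.0):
            hits.append(n)
    return hits


# -- per-participant simulation --------------------------------------------

def _draw_gain_weeks(config: SimConfig, magnitudes: Sequence[float],
                     duration: int, baseline: float, slope: float,
                     rng: np.random.Generator,
                     max_week: int | None = None) -> list[int]:
    """Sample non-interfering pre-gain weeks, one per injected gain.

    Weeks are drawn from the configured weight distribution restricted
    to weeks where the relative-drop criterion is attainable for that
    gain's magnitude (the expected pre-gain score must not exceed four
    times the realisable drop, allowing for the weekly slope and about
    one SD of week-to-week noise).  A small gain therefore lands late,
    where the symptom level has already come down — which is also how
    small qualifying gains arise in observed trajectories.
    """
    sd_diff = math.sqrt(2.0 * (1.0 - config.ar_coef)) * (
        config.innovation_sd / math.sqrt(1.0 - config.ar_coef**2)
        if config.innovation_sd else 0.0
    )
    last = duration - 2 if max_week is None else min(duration - 2, max_week)
    cand = [(w, p) for w, p in config.pre_gain_week_weights if 2 <= w <= last]
    if not cand:
        raise SimulationError(f"no candidate pre-gain week for duration {duration}")
    weeks_arr = np.array([w for w, _ in cand])
    probs = np.array([p for _, p in cand], dtype=float)
    probs /= probs.sum()
    for _ in range(300):
        proposal = [int(rng.choice(weeks_arr, p=probs)) for _ in magnitudes]
        ws = sorted(proposal)
        if len(set(ws)) < len(ws) or any(b - a < 3 for a, b in zip(ws, ws[1:])):
            continue
        ok = True
        for i, (w, mag) in enumerate(zip(proposal, magnitudes)):
            # expected symptom level just before this gain, net of any
            # earlier injected step on the same trajectory
            level = baseline - slope * (w - 1) - sum(
                m for j, m in enumerate(magnitudes) if proposal[j] < w
            )
            if not config.pct_feasibility(level, mag, slope, sd_diff):
                ok = False
                break
            # headroom: the pre-gain score must clear the cutoff and the
            # drop must not be swallowed by the scale floor at zero
            if level < config.criteria.cutoff + 2.0 or level - mag - slope < -2.0:
                ok = False
                break
        if ok:
            return proposal
    raise SimulationError(
        f"no feasible gain placement (duration {duration}, baseline "
        f"{baseline:.1f}, magnitudes {[round(m, 1) for m in magnitudes]})"
    )


def simulate_trajectory(
    config: SimConfig,
    n_gains: int,
    rng: np.random.Generator,
    want_reversal: bool = False,
) -> tuple[dict[int, float], pd.DataFrame, int]:
    """One certified LSAS trajectory.

    Returns ``(series, truth, duration)`` where ``series`` maps observed
    week -> integer LSAS value and ``truth`` has one row per injected
    gain (pre-gain week, injected step magnitude, realised interval
    drop, reversal flag).  Resamples noise/missingness (and, every ten
    failures, the gain plan) until the brute-force checker certifies
    that the qualifying intervals are exactly the injected ones.
    """
    config.validate()
    sg = n_gains > 0
    duration = int(round(_trunc_normal(rng, config.duration_mean, config.duration_sd,
                                       *map(float, config.duration_range))))
    lo_base, hi_base = config.baseline_bounds
    if n_gains >= 2:
        # two qualifying 12+-point drops need enough initial severity
        lo_base = max(lo_base, 60.0)
    baseline = _trunc_normal(
        rng,
        config.baseline_mean_sg if sg else config.baseline_mean_nosg,
        config.baseline_sd_sg if sg else config.baseline_sd_nosg,
        lo_base, hi_base,
    )
    slope = config.slope_sg if sg else config.slope_nosg

    # The step magnitudes are the participant's own; certification
    # resamples weeks and noise around them, so the magnitude
    # distribution stays close to the configured one (a small gain
    # simply lands where the symptom level has fallen enough for the
    # relative-drop criterion to be attainable).  The per-trajectory
    # floor keeps the draw feasible: on a trajectory whose lowest
    # attainable pre-gain score is s, the relative-drop criterion needs
    # roughly 0.25*s, part of which the weekly slope and noise provide.
    last_candidate_week = min(duration - 2,
                              max(w for w, _ in config.pre_gain_week_weights))
    lowest_score = baseline - slope * (last_candidate_week - 1)
    traj_floor = max(config.magnitude_min,
                     config.criteria.pct * lowest_score - slope - 4.0)
    gain_weeks: list[int] = []
    magnitudes = [_draw_magnitude(rng, config, traj_floor) for _ in range(n_gains)]
    for attempt in range(config.max_attempts):
        if sg and (attempt % 10 == 0 or not gain_weeks):
            try:
                gain_weeks = _draw_gain_weeks(
                    config, magnitudes, duration, baseline, slope, rng,
                    max_week=duration - 4 if want_reversal else None)
            except SimulationError:
                # no placement for these magnitudes on this trajectory
                # (too small for the relative-drop rule, or too large
                # for the headroom above the scale floor): redraw them
                gain_weeks = []
                magnitudes = [_draw_magnitude(rng, config, traj_floor)
                              for _ in range(n_gains)]
                continue
        noise = ar1_noise(rng, duration, config.ar_coef, config.innovation_sd)
        values = np.empty(duration)
        for i, week in enumerate(range(1, duration + 1)):
            level = baseline - slope * (week - 1)
            for gw, mag in zip(gain_weeks, magnitudes):
                if week >= gw + 1:
                    level -= mag
                if want_reversal and week >= gw + 4:
                    # rebound crossing the 50%-loss threshold, then a
                    # decay gentle enough not to qualify as a new gain.
                    # The lost fraction is taken of the whole drop since
                    # the gain (step plus accumulated gradual slope), so
                    # the rebound clears the threshold despite the
                    # continuing weekly improvement underneath it.
                    k = week - (gw + 4)
                    decay = {0: 0.85, 1: 0.62, 2: 0.44, 3: 0.30,
                             4: 0.19, 5: 0.10, 6: 0.04}.get(k, 0.0)
                    level += decay * (mag + slope * (week - (gw + 1)))
            values[i] = level + noise[i]
        values = np.clip(np.rint(values), 0, 144)

        protected = {1}
        for gw in gain_weeks:
            protected.update((gw, gw + 1))
        series = {}
        for i, week in enumerate(range(1, duration + 1)):
            if week not in protected and rng.random() < config.missing_rate:
                continue
            series[week] = float(values[i])
        if len(series) < config.min_observed_lsas:
            continue

        hits = _qualifying_intervals(series, duration, config.criteria)
        if sorted(hits) != sorted(gain_weeks):
            continue
        if want_reversal and gain_weeks:
            thresh = {gw: series[gw + 1] + 0.5 * (series[gw] - series[gw + 1])
                      for gw in gain_weeks}
            if not all(any(series.get(w, -1e9) >= thresh[gw]
                           for w in range(gw + 2, duration + 1))
                       for gw in gain_weeks):
                continue
        truth_rows = [
            {"n": gw, "magnitude": mag,
             "realized_magnitude": series[gw] - series[gw + 1],
             "reversed": want_reversal}
            for gw, mag in zip(gain_weeks, magnitudes)
        ]
        return series, pd.DataFrame(truth_rows,
                                    columns=["n", "magnitude", "realized_magnitude", "reversed"]), duration
    raise SimulationError(
        f"certification failed after {config.max_attempts} attempts "
        f"(n_gains={n_gains}, duration={duration}, baseline={baseline:.1f})"
    )


def _simulate_process(
    config: SimConfig,
    duration: int,
    primary_week: int | None,
    registry: Mapping[str, MeasureSpec],
    rng: np.random.Generator,
) -> list[tuple[int, str, float]]:
    """Weekly process-measure values for one participant."""
    rows = []
    for name, spec in config.process.items():
        meas = registry[name]
        b = rng.normal(0.0, spec.between_sd)
        for week in range(1, duration + 1):
            level = spec.level + b - spec.slope * (week - 1)
            if primary_week is not None:
                for shift, amount in spec.drops:
                    if week >= primary_week + shift:
                        level -= amount
            value = level + rng.normal(0.0, spec.resid_sd)
            value = float(np.clip(np.rint(value), meas.min_value, meas.max_value))
            if rng.random() >= config.missing_rate:
                rows.append((week, name, value))
    return rows


def simulate_around_gain(
    config: SimConfig,
    measure: str,
    n_participants: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Around-gain long table for one process measure, generated directly.

    Equivalent to extracting offsets n-2..n+3 from full trajectories of
    gain participants, with the gain placed mid-series so no offset is
    clipped; used for focused power/recovery studies of the process
    models without simulating whole cohorts.
    """
    from .around import TIMEPOINTS

    spec = config.process[measure]
    registry = default_registry()
    meas = registry[measure]
    n0 = 5  # nominal pre-gain week; offsets span weeks 3..8
    rows = []
    for i in range(n_participants):
        pid = f"S{i + 1:03d}"
        b = rng.normal(0.0, spec.between_sd)
        for label, off in zip(TIMEPOINTS, (-2, -1, 0, 1, 2, 3)):
            week = n0 + off
            level = spec.level + b - spec.slope * (week - 1)
            for shift, amount in spec.drops:
                if week >= n0 + shift:
                    level -= amount
            value = level + rng.normal(0.0, spec.resid_sd)
            value = float(np.clip(np.rint(value), meas.min_value, meas.max_value))
            rows.append({"participant_id": pid, "measure": measure,
                         "timepoint": label, "value": value})
    return pd.DataFrame(rows)


# -- cohort-level simulation -----------------------------------------------

def simulate_cohort(
    config: SimConfig = SimConfig(),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    gains_per_participant: Sequence[int] | None = None,
) -> SimCohort:
    """A full certified cohort with LSAS, process measures and endpoints.

    ``gains_per_participant`` fixes the number of injected gains for
    each participant (used by the replication fixture); otherwise the
    counts are drawn from ``gain_prevalence`` and ``p_second_gain``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    registry = default_registry()

    if gains_per_participant is None:
        gains_per_participant = [
            (1 + int(rng.random() < config.p_second_gain))
            if rng.random() < config.gain_prevalence else 0
            for _ in range(config.n_participants)
        ]
    elif len(gains_per_participant) != config.n_participants:
        raise ValueError("gains_per_participant length must equal n_participants")

    width = len(str(config.n_participants))
    data_rows = []
    truth_rows = []
    endpoint_rows = []
    for i, n_gains in enumerate(gains_per_participant):
        pid = f"P{i + 1:0{width}d}"
        want_rev = n_gains > 0 and rng.random() < config.reversal_rate
        series, truth, duration = simulate_trajectory(config, n_gains, rng,
                                                      want_reversal=want_rev)
        for week, value in sorted(series.items()):
            data_rows.append((pid, week, LSAS, value))
        primary_week = None
        if not truth.empty:
            primary = truth.sort_values(["realized_magnitude", "n"],
                                        ascending=[False, True]).iloc[0]
            primary_week = int(primary["n"])
            for _, row in truth.iterrows():
                truth_rows.append({"participant_id": pid, **row.to_dict()})
        for week, name, value in _simulate_process(config, duration, primary_week,
                                                   registry, rng):
            data_rows.append((pid, week, name, value))

        post = series[max(series)]
        extra = (config.followup_extra_drop_sg if n_gains
                 else config.followup_extra_drop_nosg)
        fu = float(np.clip(np.rint(post - extra + rng.normal(0.0, config.followup_noise_sd)),
                           0, 144))
        endpoint_rows.append({"participant_id": pid, "lsas_post": np.nan, "lsas_fu3m": fu})

    data = pd.DataFrame(data_rows, columns=["participant_id", "week", "measure", "value"])
    truth_df = pd.DataFrame(
        truth_rows,
        columns=["participant_id", "n", "magnitude", "realized_magnitude", "reversed"],
    )
    cohort = Cohort(data=data, endpoints=pd.DataFrame(endpoint_rows), registry=registry)
    return SimCohort(cohort=cohort, truth=truth_df, config=config)


def make_replication_fixture(seed: int = FIXTURE_SEED,
                             config: SimConfig | None = None) -> SimCohort:
    """The 146-participant replication fixture.

    Gains are injected for fixed per-participant subsets — 89
    participants with none, 44 with exactly one, 13 with exactly two —
    so the cohort carries 57 gain participants (39%) and 70 gains in
    total by construction, each certified by the brute-force checker.
    The assignment order is shuffled by the seeded generator; the
    counts are invariant to the seed.
    """
    if config is None:
        config = SimConfig()
    if config.n_participants != 146:
        raise ValueError("the replication fixture has exactly 146 participants")
    rng = np.random.default_rng(seed)
    plan = [0] * 89 + [1] * 44 + [2] * 13
    rng.shuffle(plan)
    return simulate_cohort(config, rng=rng, gains_per_participant=plan)
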
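"""Cohorts of weekly measurement trajectories: I/O, validation, filtering.

The central container is :class:`Cohort`, a thin wrapper around a long
pandas DataFrame with one row per observed (participant, week, measure)
triple, plus an optional endpoints table carrying post-intervention and
3-month follow-up LSAS scores.  Weeks are 1-based consecutive integers;
a participant's series may end at any week.  Missing values are simply
absent rows (or empty cells in the wide layout) — never zeros, and no
imputation is performed anywhere downstream.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .measures import LSAS, MeasureSpec, default_registry

LONG_COLUMNS = ["participant_id", "week", "measure", "value"]


class CohortValidationError(ValueError):
    """Raised when an input table violates the cohort contract."""


@dataclass
class Cohort:
    """A validated cohort of weekly trajectories.

    Parameters
    ----------
    data
        Long table with columns ``participant_id, week, measure, value``;
        only observed (non-missing) values are stored.
    endpoints
        Optional table ``participant_id, lsas_post, lsas_fu3m``.
    registry
        Measure registry used for range validation.
    """

    data: pd.DataFrame
    endpoints: pd.DataFrame | None = None
    registry: dict[str, MeasureSpec] = field(default_factory=default_registry)

    def __post_init__(self) -> None:
        self.data = _validate_long(self.data, self.registry)
        if self.endpoints is not None:
            self.endpoints = self.endpoints.reset_index(drop=True)

    # -- accessors ---------------------------------------------------------

    @property
    def participants(self) -> list[str]:
        return sorted(self.data["participant_id"].unique().tolist())

    @property
    def n_participants(self) -> int:
        return self.data["participant_id"].nunique()

    def series(self, participant_id: str, measure: str = LSAS) -> dict[int, float]:
        """Observed values for one participant/measure as {week: value}."""
        sub = self.data[
            (self.data["participant_id"] == participant_id)
            & (self.data["measure"] == measure)
        ]
        return dict(zip(sub["week"].astype(int), sub["value"].astype(float)))

    def n_weeks(self, participant_id: str) -> int:
        """Length of the participant's series = last week with any record."""
        sub = self.data[self.data["participant_id"] == participant_id]
        return 0 if sub.empty else int(sub["week"].max())

    def n_lsas_points(self, participant_id: str) -> int:
        return len(self.series(participant_id, LSAS))

    def baseline_lsas(self, participant_id: str) -> float | None:
        return self.series(participant_id, LSAS).get(1)

    def post_lsas(self, participant_id: str) -> float | None:
        """Post-intervention LSAS: explicit endpoint if supplied, else the
        last observed weekly value (the study design has no operational
        end-of-treatment assessment, so the final weekly score stands in)."""
        if self.endpoints is not None:
            row = self.endpoints[self.endpoints["participant_id"] == participant_id]
            if not row.empty and pd.notna(row["lsas_post"].iloc[0]):
                return float(row["lsas_post"].iloc[0])
        s = self.series(participant_id, LSAS)
        return s[max(s)] if s else None

    def followup_lsas(self, participant_id: str) -> float | None:
        if self.endpoints is None:
            return None
        row = self.endpoints[self.endpoints["participant_id"] == participant_id]
        if row.empty or pd.isna(row["lsas_fu3m"].iloc[0]):
            return None
        return float(row["lsas_fu3m"].iloc[0])

    def metadata(self) -> pd.DataFrame:
        """Per-participant n_weeks and n_lsas_points."""
        rows = [
            {
                "participant_id": pid,
                "n_weeks": self.n_weeks(pid),
                "n_lsas_points": self.n_lsas_points(pid),
            }
            for pid in self.participants
        ]
        return pd.DataFrame(rows, columns=["participant_id", "n_weeks", "n_lsas_points"])

    def subset(self, participant_ids: Iterable[str]) -> "Cohort":
        ids = set(participant_ids)
        data = self.data[self.data["participant_id"].isin(ids)].reset_index(drop=True)
        endpoints = None
        if self.endpoints is not None:
            endpoints = self.endpoints[
                self.endpoints["participant_id"].isin(ids)
            ].reset_index(drop=True)
        return Cohort(data=data, endpoints=endpoints, registry=self.registry)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        a = self.data.sort_values(LONG_COLUMNS).reset_index(drop=True)
        b = other.data.sort_values(LONG_COLUMNS).reset_index(drop=True)
        return a.equals(b)


def _validate_long(df: pd.DataFrame, registry: Mapping[str, MeasureSpec]) -> pd.DataFrame:
    missing_cols = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"long table missing columns {missing_cols}")
    df = df.loc[:, LONG_COLUMNS].copy()
    df = df[pd.notna(df["value"])]
    df["participant_id"] = df["participant_id"].astype(str)
    weeks = pd.to_numeric(df["week"], errors="coerce")
    if weeks.isna().any():
        bad = df.loc[weeks.isna()].index[0]
        raise CohortValidationError(f"non-numeric week at row {bad}")
    if (weeks <= 0).any() or (weeks != weeks.round()).any():
        bad = df.loc[(weeks <= 0) | (weeks != weeks.round())].index[0]
        raise CohortValidationError(
            f"weeks must be positive integers; offending row {bad}"
        )
    df["week"] = weeks.astype(int)
    df["value"] = pd.to_numeric(df["value"], errors="coerce").astype(float)
    if df["value"].isna().any():
        bad = df.loc[df["value"].isna()].index[0]
        raise CohortValidationError(f"non-numeric value at row {bad}")

    unknown = set(df["measure"]) - set(registry)
    if unknown:
        raise CohortValidationError(f"unknown measure name(s): {sorted(unknown)}")

    dup = df.duplicated(subset=["participant_id", "week", "measure"], keep=False)
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise CohortValidationError(
            "duplicate record for participant "
            f"{first['participant_id']!r} week {first['week']} "
            f"measure {first['measure']!r}"
        )

    for name, spec in registry.items():
        vals = df.loc[df["measure"] == name, "value"]
        out = vals[(vals < spec.min_value) | (vals > spec.max_value)]
        if not out.empty:
            raise CohortValidationError(
                f"measure {name!r}: value {out.iloc[0]} outside "
                f"[{spec.min_value}, {spec.max_value}]"
            )
    return df.sort_values(LONG_COLUMNS).reset_index(drop=True)


# -- readers / writers -----------------------------------------------------

_WIDE_RE = re.compile(r"^(?P<measure>.+)_w(?P<week>\d+)$")


def read_cohort(
    path: str | Path | io.TextIOBase,
    format: str = "long",
    registry: Mapping[str, MeasureSpec] | None = None,
    endpoints_path: str | Path | None = None,
) -> Cohort:
    """Read a cohort from a long or wide CSV file.

    Long layout: columns ``participant_id,week,measure,value`` with an
    empty value cell meaning missing.  Wide layout: ``participant_id``
    plus one ``<measure>_w<k>`` column per measure-week.  Out-of-range
    values raise a :class:`CohortValidationError` naming the offender;
    nothing is clamped silently.
    """
    registry = dict(registry) if registry is not None else default_registry()
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message
        raise CohortValidationError(f"malformed CSV: {exc}") from exc

    if format == "long":
        raw = raw.replace({"value": {"": None}})
        long = raw
    elif format == "wide":
        long = _wide_to_long(raw)
    else:
        raise ValueError(f"format must be 'long' or 'wide', got {format!r}")

    endpoints = None
    if endpoints_path is not None:
        endpoints = read_endpoints(endpoints_path)
    return Cohort(data=long, endpoints=endpoints, registry=registry)


def _wide_to_long(raw: pd.DataFrame) -> pd.DataFrame:
    if "participant_id" not in raw.columns:
        raise CohortValidationError("wide table needs a participant_id column")
    records = []
    for col in raw.columns:
        if col == "participant_id":
            continue
        m = _WIDE_RE.match(col)
        if m is None:
            raise CohortValidationError(
                f"wide column {col!r} does not match <measure>_w<week>"
            )
        measure, week = m["measure"], int(m["week"])
        for pid, val in zip(raw["participant_id"], raw[col]):
            if val == "":
                continue
            records.append((pid, week, measure, val))
    return pd.DataFrame(records, columns=LONG_COLUMNS)


def read_endpoints(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    needed = {"participant_id", "lsas_post", "lsas_fu3m"}
    if not needed <= set(df.columns):
        raise CohortValidationError(
            f"endpoints file must have columns {sorted(needed)}"
        )
    df["participant_id"] = df["participant_id"].astype(str)
    return df


def write_cohort(cohort: Cohort, path: str | Path, format: str = "long") -> None:
    """Write a cohort back to CSV in either layout (round-trip safe)."""
    if format == "long":
        cohort.data.to_csv(path, index=False)
    elif format == "wide":
        wide = cohort.data.copy()
        wide["col"] = wide["measure"] + "_w" + wide["week"].astype(str)
        table = wide.pivot(index="participant_id", columns="col", values="value")
        # order columns measure-major, week-minor for readability
        def _key(c: str) -> tuple[str, int]:
            m = _WIDE_RE.match(c)
            return (m["measure"], int(m["week"]))
        table = table[sorted(table.columns, key=_key)]
        table.to_csv(path, index=True)
    else:
        raise ValueError(f"format must be 'long' or 'wide', got {format!r}")


# -- inclusion filter ------------------------------------------------------

def apply_inclusion_filter(
    cohort: Cohort, min_lsas_points: int = 8
) -> tuple[Cohort, Cohort, dict]:
    """Split a cohort by the minimum-data rule.

    Participants with fewer than ``min_lsas_points`` non-missing weekly
    LSAS values are excluded: too few datapoints both to reflect an
    adequate dose of therapy and to support the stability criterion's
    windowed comparisons.  Returns (included, excluded, report); the two
    parts partition the input.
    """
    if min_lsas_points < 1:
        raise ValueError("min_lsas_points must be >= 1")
    meta = cohort.metadata()
    keep = meta.loc[meta["n_lsas_points"] >= min_lsas_points, "participant_id"]
    drop = meta.loc[meta["n_lsas_points"] < min_lsas_points, "participant_id"]
    included = cohort.subset(keep)
    excluded = cohort.subset(drop)
    report = {
        "n_total": int(len(meta)),
        "n_included": int(len(keep)),
        "n_excluded": int(len(drop)),
        "min_lsas_points": int(min_lsas_points),
    }
    return included, excluded, report
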
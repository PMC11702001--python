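"""Cohort container, CSV round-trips and the inclusion filter."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import suddengain as sg
from suddengain.trajectory import CohortValidationError


def _long_csv(text: str) -> io.StringIO:
    return io.StringIO(text)


class TestReadCohort:
    def test_long_read_preserves_rows(self):
        csv = _long_csv(
            "participant_id,week,measure,value\n"
            "p1,1,lsas,80\np1,2,lsas,75\np1,3,lsas,70\n"
            "p2,1,lsas,90\np2,2,lsas,85\np2,3,lsas,82\n"
        )
        cohort = sg.read_cohort(csv, format="long")
        assert len(cohort.data) == 6
        assert cohort.participants == ["p1", "p2"]

    def test_empty_value_means_missing(self):
        csv = _long_csv(
            "participant_id,week,measure,value\n"
            "p1,1,lsas,80\np1,2,lsas,\np1,3,lsas,70\n"
        )
        cohort = sg.read_cohort(csv, format="long")
        assert cohort.series("p1") == {1: 80.0, 3: 70.0}

    def test_out_of_range_value_rejected(self):
        csv = _long_csv("participant_id,week,measure,value\np1,1,lsas,150\n")
        with pytest.raises(CohortValidationError, match="lsas"):
            sg.read_cohort(csv, format="long")

    def test_duplicate_record_rejected(self):
        csv = _long_csv(
            "participant_id,week,measure,value\np1,1,lsas,80\np1,1,lsas,81\n"
        )
        with pytest.raises(CohortValidationError, match="duplicate"):
            sg.read_cohort(csv, format="long")

    def test_unknown_measure_rejected(self):
        csv = _long_csv("participant_id,week,measure,value\np1,1,bogus,3\n")
        with pytest.raises(CohortValidationError, match="bogus"):
            sg.read_cohort(csv, format="long")

    def test_nonpositive_week_rejected(self):
        csv = _long_csv("participant_id,week,measure,value\np1,0,lsas,80\n")
        with pytest.raises(CohortValidationError, match="positive"):
            sg.read_cohort(csv, format="long")


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["long", "wide"])
    def test_write_read_identity(self, tmp_path, fmt, fixture_cohort):
        path = tmp_path / f"cohort_{fmt}.csv"
        sg.write_cohort(fixture_cohort.cohort, path, format=fmt)
        back = sg.read_cohort(path, format=fmt)
        assert back == fixture_cohort.cohort

    def test_wide_layout_round_trip_small(self, tmp_path, small_cohort):
        path = tmp_path / "wide.csv"
        sg.write_cohort(small_cohort, path, format="wide")
        back = sg.read_cohort(path, format="wide")
        assert back == small_cohort


class TestInclusionFilter:
    @staticmethod
    def _cohort_with_points(counts: dict[str, int]) -> sg.Cohort:
        rows = [
            (pid, w, sg.LSAS, 80)
            for pid, k in counts.items()
            for w in range(1, k + 1)
        ]
        return sg.Cohort(pd.DataFrame(rows, columns=["participant_id", "week",
                                                     "measure", "value"]))

    def test_boundary_at_minimum(self):
        cohort = self._cohort_with_points({"eight": 8, "seven": 7})
        inc, exc, report = sg.apply_inclusion_filter(cohort, 8)
        assert inc.participants == ["eight"]
        assert exc.participants == ["seven"]
        assert report == {"n_total": 2, "n_included": 1, "n_excluded": 1,
                          "min_lsas_points": 8}

    def test_missingness_counts_not_duration(self):
        # 14 weeks of records but only 5 observed LSAS values
        rows = [("p", w, sg.LSAS, 85) for w in (1, 4, 7, 10, 14)]
        rows += [("p", w, sg.PHQ9, 9) for w in range(1, 15)]
        cohort = sg.Cohort(pd.DataFrame(rows, columns=["participant_id", "week",
                                                       "measure", "value"]))
        inc, exc, _ = sg.apply_inclusion_filter(cohort, 8)
        assert inc.n_participants == 0
        assert exc.participants == ["p"]

    def test_empty_cohort_is_not_an_error(self):
        cohort = sg.Cohort(pd.DataFrame(columns=["participant_id", "week",
                                                 "measure", "value"]))
        inc, exc, report = sg.apply_inclusion_filter(cohort, 8)
        assert report["n_total"] == 0
        assert inc.n_participants == 0 and exc.n_participants == 0

    @given(counts=st.dictionaries(
        st.text(alphabet="abcdefgh", min_size=1, max_size=3),
        st.integers(min_value=1, max_value=12), max_size=6))
    @settings(max_examples=30, deadline=None)
    def test_partition_and_idempotence(self, counts):
        cohort = self._cohort_with_points(counts)
        inc, exc, _ = sg.apply_inclusion_filter(cohort, 8)
        assert set(inc.participants) | set(exc.participants) == set(counts)
        assert not set(inc.participants) & set(exc.participants)
        inc2, exc2, _ = sg.apply_inclusion_filter(inc, 8)
        assert inc2.participants == inc.participants
        assert exc2.n_participants == 0


class TestEndpoints:
    def test_post_defaults_to_last_observed_week(self, small_cohort):
        assert small_cohort.post_lsas("A") == 30
        assert small_cohort.post_lsas("C") == 90

    def test_explicit_endpoint_overrides(self, small_cohort):
        endpoints = pd.DataFrame(
            {"participant_id": ["A"], "lsas_post": [25.0], "lsas_fu3m": [20.0]}
        )
        cohort = sg.Cohort(data=small_cohort.data, endpoints=endpoints)
        assert cohort.post_lsas("A") == 25.0
        assert cohort.followup_lsas("A") == 20.0
        assert cohort.followup_lsas("B") is None
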
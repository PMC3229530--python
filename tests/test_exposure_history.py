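"""Exposure classification and person-time splitting against a
day-resolution brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tzdcohort.exposure_history import (
    assert_no_immortal_time,
    attribute_events,
    classify_exposure,
    split_person_time,
)

from conftest import day_loop_state


def make_patients(ids, birth_year=1940):
    n = len(ids)
    return pd.DataFrame({
        "patient_id": ids,
        "birth_year": birth_year,
        "data_start": 0,
        "data_end": 10_000,
        "type1": False,
    })


def rx_frame(patient_id, days, drug_class="rosiglitazone"):
    return pd.DataFrame({
        "patient_id": patient_id,
        "day": list(days),
        "drug_class": drug_class,
        "multi_constituent": "",
    })


class TestClassifyExposure:
    @pytest.mark.parametrize("query,expected", [
        (45, "current"), (200, "recent"), (400, "past"),
        (0, "current"), (90, "current"), (91, "recent"),
        (364, "recent"), (365, "past"), (-1, "never"),
    ])
    def test_single_prescription_cut_points(self, query, expected):
        """3-month and 12-month windows from a single prescription at day 0."""
        assert classify_exposure([0], query) == expected

    def test_no_prescriptions_is_never_everywhere(self):
        for day in (-5, 0, 100, 10_000):
            assert classify_exposure([], day) == "never"

    def test_repeat_prescription_extends_current_window(self):
        """Rx at day 0 and 60: current throughout [0, 151), incl. day 100."""
        rx = [0, 60]
        for day in range(0, 151):
            assert classify_exposure(rx, day) == "current"
        assert classify_exposure(rx, 151) == "recent"

    @given(st.lists(st.integers(0, 1500), max_size=8),
           st.integers(-10, 2000))
    @settings(max_examples=200, deadline=None)
    def test_matches_day_loop_oracle(self, rx_days, day):
        assert classify_exposure(rx_days, day) == day_loop_state(rx_days, day)


class TestSplitPersonTime:
    def test_single_rx_three_segments(self):
        """One Rx, 400 days of follow-up: [0,91) current, [91,365) recent,
        [365,400) past; durations sum to 400."""
        cohort = pd.DataFrame({"patient_id": [1], "index_day": [0],
                               "censor_day": [400]})
        # birth year chosen so no age-band birthday falls inside follow-up
        patients = make_patients([1], birth_year=1935)
        seg = split_person_time(cohort, rx_frame(1, [0]), patients,
                                classes=("rosiglitazone",))
        assert list(seg["start"]) == [0, 91, 365]
        assert list(seg["end"]) == [91, 365, 400]
        assert list(seg["state_rosiglitazone"]) == ["current", "recent", "past"]
        assert seg["duration"].sum() == 400

    def test_reference_class_censoring(self):
        """Starting the comparator at day 300 ends person-time at day 300."""
        cohort = pd.DataFrame({"patient_id": [1], "index_day": [0],
                               "censor_day": [900]})
        rx = pd.concat([rx_frame(1, [0], "rosiglitazone"),
                        rx_frame(1, [300], "pioglitazone")], ignore_index=True)
        seg = split_person_time(cohort, rx, make_patients([1]),
                                reference_class="pioglitazone")
        assert seg["end"].max() == 300
        assert seg["duration"].sum() == 300

    def test_reference_started_before_index_drops_patient(self):
        cohort = pd.DataFrame({"patient_id": [1], "index_day": [500],
                               "censor_day": [900]})
        rx = rx_frame(1, [100], "pioglitazone")
        seg = split_person_time(cohort, rx, make_patients([1]),
                                reference_class="pioglitazone")
        assert seg.empty

    def test_unsorted_and_duplicate_prescriptions_are_legal(self):
        cohort = pd.DataFrame({"patient_id": [1], "index_day": [0],
                               "censor_day": [600]})
        tidy = split_person_time(cohort, rx_frame(1, [10, 200]),
                                 make_patients([1]),
                                 classes=("rosiglitazone",))
        messy = split_person_time(cohort, rx_frame(1, [200, 10, 10, 200]),
                                  make_patients([1]),
                                  classes=("rosiglitazone",))
        pd.testing.assert_frame_equal(tidy, messy)

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_tiling_and_oracle_on_random_streams(self, data):
        """Segments tile [index, censor) exactly and every segment's label
        agrees with the day-loop classifier at segment start and end-1."""
        n_rx = data.draw(st.integers(0, 10))
        rx_days = data.draw(st.lists(st.integers(0, 1400), min_size=n_rx,
                                     max_size=n_rx))
        index = data.draw(st.integers(0, 200))
        censor = data.draw(st.integers(index + 1, 1600))
        cohort = pd.DataFrame({"patient_id": [1], "index_day": [index],
                               "censor_day": [censor]})
        seg = split_person_time(cohort, rx_frame(1, rx_days),
                                make_patients([1], birth_year=1900),
                                classes=("rosiglitazone",))
        # conservation
        assert seg["duration"].sum() == censor - index
        assert seg["start"].min() == index
        assert seg["end"].max() == censor
        assert (seg["start"] < seg["end"]).all()
        # disjoint, ordered tiling
        assert (seg["start"].to_numpy()[1:] == seg["end"].to_numpy()[:-1]).all()
        # oracle agreement at both ends of each segment
        for _, row in seg.iterrows():
            for day in (row["start"], row["end"] - 1):
                assert row["state_rosiglitazone"] == day_loop_state(rx_days, day)

    def test_monotone_state_order_after_last_rx(self):
        cohort = pd.DataFrame({"patient_id": [1], "index_day": [0],
                               "censor_day": [1500]})
        seg = split_person_time(cohort, rx_frame(1, [50, 120, 180]),
                                make_patients([1], birth_year=1900),
                                classes=("rosiglitazone",))
        states = seg["state_rosiglitazone"].tolist()
        order = {"never": 0, "current": 1, "recent": 2, "past": 3}
        after_first = states[states.index("current"):]
        assert [order[s] for s in after_first] == sorted(
            order[s] for s in after_first)


class TestCovariateSnapshots:
    def test_most_recent_value_before_segment_start(self):
        cohort = pd.DataFrame({"patient_id": [1], "index_day": [100],
                               "censor_day": [500]})
        cov = pd.DataFrame({
            "patient_id": [1, 1], "day": [0, 250],
            "covariate": ["smoking", "smoking"], "value": ["non", "current"],
        })
        seg = split_person_time(cohort, rx_frame(1, []), make_patients([1]),
                                covariates=cov, classes=("rosiglitazone",))
        assert seg.loc[seg["start"] < 250, "smoking"].eq("non").all()
        assert seg.loc[seg["start"] >= 250, "smoking"].eq("current").all()

    def test_comedication_expires_after_183_days(self):
        cohort = pd.DataFrame({"patient_id": [1], "index_day": [0],
                               "censor_day": [500]})
        cov = pd.DataFrame({"patient_id": [1], "day": [0],
                            "covariate": ["statins"], "value": ["yes"]})
        seg = split_person_time(cohort, rx_frame(1, []), make_patients([1]),
                                covariates=cov, classes=("rosiglitazone",))
        assert seg.loc[seg["start"] < 183, "statins"].eq("yes").all()
        assert seg.loc[seg["start"] >= 183, "statins"].eq("none").all()


class TestAttributeEvents:
    def _segments(self):
        cohort = pd.DataFrame({"patient_id": [1], "index_day": [0],
                               "censor_day": [400]})
        return split_person_time(cohort, rx_frame(1, [0]), make_patients([1]),
                                 classes=("rosiglitazone",))

    def test_terminal_event_truncates_containing_segment(self):
        """Death on day 100 of the [91, 365) recent segment: counted there
        and the segment shrinks to [91, 101)."""
        seg = attribute_events(
            self._segments(),
            pd.DataFrame({"patient_id": [1], "day": [100]}),
            incident_only=False, terminal=True,
        )
        hit = seg[seg["events"] == 1]
        assert len(hit) == 1
        assert (hit["start"].iloc[0], hit["end"].iloc[0]) == (91, 101)
        assert seg["end"].max() == 101

    def test_event_on_segment_boundary_belongs_to_right_segment(self):
        seg = attribute_events(
            self._segments(),
            pd.DataFrame({"patient_id": [1], "day": [91]}),
            incident_only=False,
        )
        hit = seg[seg["events"] == 1]
        assert hit["start"].iloc[0] == 91

    def test_pre_index_event_excludes_patient_from_outcome(self):
        cohort = pd.DataFrame({"patient_id": [1], "index_day": [200],
                               "censor_day": [600]})
        seg0 = split_person_time(cohort, rx_frame(1, [200]),
                                 make_patients([1]),
                                 classes=("rosiglitazone",))
        ev = pd.DataFrame({"patient_id": [1, 1], "day": [50, 300]})
        seg = attribute_events(seg0, ev, incident_only=True)
        assert seg.empty
        kept = attribute_events(seg0, ev, incident_only=False)
        assert kept["events"].sum() == 1  # first event pre-index is ignored

    def test_only_first_event_counts(self):
        ev = pd.DataFrame({"patient_id": [1, 1, 1], "day": [50, 60, 300]})
        seg = attribute_events(self._segments(), ev, incident_only=False)
        assert seg["events"].sum() == 1
        assert seg.loc[seg["events"] == 1, "start"].iloc[0] == 0

    def test_zero_events_leaves_person_time_unchanged(self):
        seg0 = self._segments()
        seg = attribute_events(seg0, pd.DataFrame(columns=["patient_id", "day"]))
        assert seg["events"].sum() == 0
        assert seg["duration"].sum() == seg0["duration"].sum()


def test_no_immortal_time_on_generator_output(small_tables):
    """No segment is ever labelled current before the class's first Rx."""
    patients = small_tables["patients"]
    cohort = pd.DataFrame({
        "patient_id": patients["patient_id"],
        "index_day": patients["data_start"],
        "censor_day": patients["data_end"],
    }).head(300)
    seg = split_person_time(cohort, small_tables["prescriptions"], patients)
    assert_no_immortal_time(seg, small_tables["prescriptions"])
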
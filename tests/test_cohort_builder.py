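"""New-user cohort construction and matched-control selection."""

import numpy as np
import pandas as pd
import pytest

from tzdcohort.cohort_builder import (
    MatchCriteria,
    ReferentialIntegrityError,
    build_exposed_cohort,
    build_inception_cohort,
    match_controls,
)
from tzdcohort.config import ConfigurationError
from tzdcohort.timeutils import to_day


def patients_frame(rows):
    """rows: (patient_id, practice, sex, birth_year, start, end)."""
    df = pd.DataFrame(rows, columns=["patient_id", "practice_id", "sex",
                                     "birth_year", "data_start", "data_end"])
    df["data_start"] = df["data_start"].map(to_day)
    df["data_end"] = df["data_end"].map(to_day)
    df["death_day"] = pd.array([pd.NA] * len(df), dtype="Int64")
    df["death_source"] = ""
    df["type1"] = False
    df["linked"] = False
    return df


def rx_frame(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "day", "drug_class"])
    df["day"] = df["day"].map(to_day)
    df["multi_constituent"] = ""
    return df


class TestExposedCohort:
    def test_rx_within_first_year_does_not_qualify(self):
        """First OAD five months after data start, nothing later: the
        one-year run-in excludes the patient."""
        patients = patients_frame([(1, 1, "F", 1940, "2000-01-01", "2005-01-01")])
        rx = rx_frame([(1, "2000-06-01", "metformin")])
        assert build_exposed_cohort(patients, rx).empty

    def test_no_prescriptions_not_in_cohort(self):
        patients = patients_frame([(1, 1, "F", 1940, "2000-01-01", "2005-01-01")])
        rx = rx_frame([]).astype({"patient_id": "int64", "day": "int64"})
        assert build_exposed_cohort(patients, rx).empty

    def test_index_is_first_rx_after_run_in(self):
        """Early Rx ignored for the index; the 2001-03-01 Rx (>= 365 days
        after 2000-01-01) becomes the index date."""
        patients = patients_frame([(1, 1, "F", 1940, "2000-01-01", "2005-01-01")])
        rx = rx_frame([(1, "2000-06-01", "metformin"),
                       (1, "2001-03-01", "metformin")])
        assert to_day("2001-03-01") - to_day("2000-01-01") >= 365
        cohort = build_exposed_cohort(patients, rx)
        assert len(cohort) == 1
        assert cohort["index_day"].iloc[0] == to_day("2001-03-01")

    def test_under_age_and_type1_excluded(self):
        patients = patients_frame([
            (1, 1, "M", 1975, "2000-01-01", "2008-01-01"),  # age ~26 at Rx
            (2, 1, "M", 1940, "2000-01-01", "2008-01-01"),
        ])
        patients.loc[patients["patient_id"] == 2, "type1"] = True
        rx = rx_frame([(1, "2002-01-01", "insulin"), (2, "2002-01-01", "insulin")])
        assert build_exposed_cohort(patients, rx).empty

    def test_unknown_patient_reference_raises(self):
        patients = patients_frame([(1, 1, "F", 1940, "2000-01-01", "2005-01-01")])
        rx = rx_frame([(99, "2002-01-01", "metformin")])
        with pytest.raises(ReferentialIntegrityError):
            build_exposed_cohort(patients, rx)


class TestInceptionCohort:
    def test_first_ever_of_class_rule(self):
        """First metformin in year 3 qualifies for the metformin cohort even
        though sulphonylurea came first; sulphonylurea's own first-ever Rx
        inside the run-in year keeps it out of that cohort."""
        patients = patients_frame([(1, 1, "F", 1940, "1999-01-01", "2006-01-01")])
        rx = rx_frame([(1, "1999-06-01", "sulphonylurea"),
                       (1, "2001-05-01", "metformin")])
        met = build_inception_cohort(patients, rx, "metformin")
        sul = build_inception_cohort(patients, rx, "sulphonylurea")
        assert len(met) == 1 and met["index_day"].iloc[0] == to_day("2001-05-01")
        assert sul.empty

    def test_boundary_day_inclusive(self):
        """An Rx exactly 365 days after data start qualifies."""
        patients = patients_frame([(1, 1, "F", 1940, "2000-01-01", "2005-01-01")])
        rx = rx_frame([(1, "2000-12-31", "metformin")])  # day 365 of 2000 (leap)
        assert to_day("2000-12-31") - to_day("2000-01-01") == 365
        cohort = build_inception_cohort(patients, rx, "metformin")
        assert len(cohort) == 1

    def test_multi_constituent_enters_both_cohorts(self):
        patients = patients_frame([(1, 1, "F", 1940, "2000-01-01", "2006-01-01")])
        rx = rx_frame([(1, "2002-01-01", "rosiglitazone")])
        rx["multi_constituent"] = "metformin"
        rosi = build_inception_cohort(patients, rx, "rosiglitazone")
        met = build_inception_cohort(patients, rx, "metformin")
        assert len(rosi) == 1 and len(met) == 1
        assert rosi["index_day"].iloc[0] == met["index_day"].iloc[0]

    def test_unknown_drug_class_raises(self):
        patients = patients_frame([(1, 1, "F", 1940, "2000-01-01", "2005-01-01")])
        with pytest.raises(ConfigurationError):
            build_inception_cohort(patients, rx_frame([]), "statin")


class TestMatchControls:
    def _setup(self, extra_candidates=()):
        rows = [(1, 1, "F", 1940, "1999-01-01", "2008-01-01")]
        rows += list(extra_candidates)
        patients = patients_frame(rows)
        rx = rx_frame([(1, "2004-07-01", "metformin")])
        exposed = build_exposed_cohort(patients, rx)
        return patients, rx, exposed

    def test_empty_pool_flags_unmatched(self):
        patients, rx, exposed = self._setup()
        controls, flagged = match_controls(exposed, patients, rx, seed=1)
        assert controls.empty
        assert not flagged["matched"].iloc[0]

    def test_nearest_age_wins(self):
        """Exposed aged 64: candidates aged 63 (|1|) and 66 (|2|) — the
        63-year-old is selected."""
        patients, rx, exposed = self._setup([
            (2, 1, "F", 1941, "1999-01-01", "2008-01-01"),  # age 63 at 2004
            (3, 1, "F", 1938, "1999-01-01", "2008-01-01"),  # age 66
        ])
        controls, flagged = match_controls(exposed, patients, rx, seed=1)
        assert len(controls) == 1
        assert controls["patient_id"].iloc[0] == 2
        assert controls["matched_to"].iloc[0] == 1
        assert controls["index_day"].iloc[0] == exposed["index_day"].iloc[0]

    def test_age_tolerance_respected(self):
        patients, rx, exposed = self._setup([
            (2, 1, "F", 1930, "1999-01-01", "2008-01-01"),  # age 74, |diff|=10
        ])
        controls, _ = match_controls(exposed, patients, rx,
                                     MatchCriteria(age_tolerance=5), seed=1)
        assert controls.empty

    def test_sex_and_practice_must_match(self):
        patients, rx, exposed = self._setup([
            (2, 1, "M", 1940, "1999-01-01", "2008-01-01"),
            (3, 2, "F", 1940, "1999-01-01", "2008-01-01"),
        ])
        controls, _ = match_controls(exposed, patients, rx, seed=1)
        assert controls.empty

    def test_control_censored_at_own_first_oad(self):
        """A matched control who later starts an OAD contributes control
        person-time only up to that first prescription."""
        patients, rx, exposed = self._setup([
            (2, 1, "F", 1940, "1999-01-01", "2008-01-01"),
        ])
        rx2 = pd.concat([rx, rx_frame([(2, "2006-01-01", "metformin")])],
                        ignore_index=True)
        controls, _ = match_controls(exposed, patients, rx2, seed=1)
        assert len(controls) == 1
        assert controls["censor_day"].iloc[0] == to_day("2006-01-01")

    def test_prior_diabetes_rx_disqualifies_candidate(self):
        patients, rx, exposed = self._setup([
            (2, 1, "F", 1940, "1999-01-01", "2008-01-01"),
        ])
        rx2 = pd.concat([rx, rx_frame([(2, "2003-01-01", "metformin")])],
                        ignore_index=True)
        controls, _ = match_controls(exposed, patients, rx2, seed=1)
        assert controls.empty

    def test_same_seed_same_matching(self, small_tables):
        exposed = build_exposed_cohort(small_tables["patients"],
                                       small_tables["prescriptions"]).head(150)
        args = (exposed, small_tables["patients"], small_tables["prescriptions"])
        c1, _ = match_controls(*args, seed=42)
        c2, _ = match_controls(*args, seed=42)
        pd.testing.assert_frame_equal(c1, c2)

    def test_emitted_pairs_satisfy_all_criteria(self, small_tables):
        """Matching is symmetric-feasible: every emitted pair meets the
        configured criteria exactly, and controls are used at most once."""
        from tzdcohort.timeutils import age_at

        patients = small_tables["patients"].set_index("patient_id")
        exposed = build_exposed_cohort(small_tables["patients"],
                                       small_tables["prescriptions"]).head(200)
        controls, _ = match_controls(exposed, small_tables["patients"],
                                     small_tables["prescriptions"], seed=7)
        assert controls["patient_id"].is_unique
        for _, c in controls.iterrows():
            e = patients.loc[c["matched_to"]]
            ctl = patients.loc[c["patient_id"]]
            assert e["sex"] == ctl["sex"]
            assert e["practice_id"] == ctl["practice_id"]
            age_e = age_at(np.array([c["index_day"]]),
                           np.array([e["birth_year"]]))[0]
            age_c = age_at(np.array([c["index_day"]]),
                           np.array([ctl["birth_year"]]))[0]
            assert abs(age_e - age_c) <= 5
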
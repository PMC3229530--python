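"""Generator contracts: determinism, calibration, anachronism guards and
ground-truth recovery by direct simulation."""

import numpy as np
import pandas as pd
import pytest

from tzdcohort import ScenarioConfig, simulate
from tzdcohort.config import ConfigurationError
from tzdcohort.exposure_history import expand_prescriptions
from tzdcohort.synthetic_ehr import generate_outcomes, generate_population
from tzdcohort.timeutils import PERSON_YEAR_DAYS, to_day

ZERO_HAZARDS = {"death": 0.0, "acs": 0.0, "stroke": 0.0, "heart_failure": 0.0}
NO_EFFECTS = dict(
    outcome_age_coef=ZERO_HAZARDS, outcome_male_coef=ZERO_HAZARDS,
    outcome_severity_coef=ZERO_HAZARDS, outcome_comorbidity_coef=0.0,
)


def test_empty_population_guard():
    with pytest.raises(ConfigurationError):
        ScenarioConfig(n_patients=0)
    with pytest.raises(ConfigurationError):
        ScenarioConfig(n_practices=0)


def test_unknown_true_rr_key_rejected():
    with pytest.raises(ConfigurationError):
        ScenarioConfig(true_log_rr={"aspirin": {"death": 0.1}})
    cfg = ScenarioConfig(n_patients=50, n_practices=5, seed=1)
    patients, gt = generate_population(cfg)
    cfg.true_log_rr = {"rosiglitazone": {"sepsis": 0.1}}  # bypass init check
    with pytest.raises(ConfigurationError):
        generate_outcomes(patients, pd.DataFrame(
            columns=["patient_id", "day", "drug_class", "multi_constituent"]),
            cfg, gt)


def test_linkage_fraction_binomial_at_practice_level():
    """With 1000 patients over many practices and linkage fraction 0.4,
    the linked share is within 3 binomial sd of 0.4."""
    cfg = ScenarioConfig(n_patients=1000, n_practices=100,
                         linkage_fraction=0.4, seed=1)
    patients, _ = generate_population(cfg)
    frac = patients["linked"].mean()
    sd = np.sqrt(0.4 * 0.6 / cfg.n_practices)  # practice-level binomial
    assert abs(frac - 0.4) < 3 * sd


def test_determinism_same_seed_identical_tables(small_config, small_tables):
    rerun = simulate(small_config)
    for name in ("patients", "prescriptions", "events", "death_causes",
                 "covariates", "ground_truth"):
        pd.testing.assert_frame_equal(small_tables[name], rerun[name])


def test_rosiglitazone_zero_multiplier_from_2008():
    cfg = ScenarioConfig(n_patients=800, n_practices=10, seed=5)
    mults = dict(cfg.calendar_multipliers)
    mults["rosiglitazone"] = {**mults["rosiglitazone"],
                              2008: 0.0, 2009: 0.0, 2010: 0.0}
    tables = simulate(cfg.replace(calendar_multipliers=mults))
    summary = tables["summary"]
    rosi = summary[summary["drug_class"] == "rosiglitazone"]
    assert rosi[rosi["year"] >= 2008]["initiations"].sum() == 0


class TestChanneling:
    def _severity_by_initiation(self, channeling, seed=9, n=5000):
        cfg = ScenarioConfig(
            n_patients=n, n_practices=50, seed=seed,
            channeling_strength=channeling,
            outcome_baseline_hazards=ZERO_HAZARDS,
        )
        tables = simulate(cfg)
        rx = expand_prescriptions(tables["prescriptions"])
        sev = tables["ground_truth"].set_index("patient_id")["latent_severity"]
        started = rx.groupby("patient_id")["drug_class"].agg(set)
        return sev, started

    def test_no_channeling_severity_uncorrelated_with_insulin(self):
        sev, started = self._severity_by_initiation({})
        has_insulin = sev.index.to_series().map(
            lambda p: "insulin" in started.get(p, set())).astype(float)
        r = np.corrcoef(sev, has_insulin)[0, 1]
        assert abs(r) < 3 / np.sqrt(len(sev))

    def test_channeling_raises_severity_of_insulin_initiators(self):
        """Monte-Carlo generator-level oracle: with positive channeling,
        insulin initiators are sicker than metformin-only initiators."""
        sev, started = self._severity_by_initiation({"insulin": 0.8})
        groups = {"insulin": [], "metformin_only": []}
        for pid, classes in started.items():
            if "insulin" in classes:
                groups["insulin"].append(sev.loc[pid])
            elif classes == {"metformin"}:
                groups["metformin_only"].append(sev.loc[pid])
        assert np.mean(groups["insulin"]) > np.mean(groups["metformin_only"])


def test_null_hazards_no_events_everyone_survives():
    cfg = ScenarioConfig(n_patients=300, n_practices=5, seed=2,
                         outcome_baseline_hazards=ZERO_HAZARDS)
    tables = simulate(cfg)
    assert tables["events"].empty
    assert tables["patients"]["death_day"].isna().all()
    assert tables["death_causes"].empty


def test_rate_calibration_constant_hazard():
    """With all covariate effects off and constant death hazard lambda,
    total events / person-years recovers lambda within 3 MC sd."""
    lam = 0.05
    cfg = ScenarioConfig(
        n_patients=4000, n_practices=20, seed=3,
        outcome_baseline_hazards={"death": lam, "acs": 0.0, "stroke": 0.0,
                                  "heart_failure": 0.0},
        true_log_rr={}, **NO_EFFECTS,
    )
    tables = simulate(cfg)
    patients = tables["patients"]
    end = np.where(patients["death_day"].notna(),
                   patients["death_day"].astype("float64") + 1,
                   patients["data_end"])
    py = (end - patients["data_start"]).sum() / PERSON_YEAR_DAYS
    events = patients["death_day"].notna().sum()
    rate = events / py
    sd = np.sqrt(events) / py
    assert abs(rate - lam) < 3 * sd


def test_crude_death_rate_ratio_recovers_true_rr():
    """Direct-simulation oracle: true current-use death RR 1.2 for
    rosiglitazone, no confounding — the crude rosi:pio rate ratio during
    current use lands within 3 sd of 1.2."""
    from tzdcohort import scenarios
    from tzdcohort.exposure_history import attribute_events, split_person_time
    from tzdcohort.orchestrator import (
        CURRENT_LEVELS, build_tzd_segments, death_event_table,
    )
    from tzdcohort.rate_models import aggregate, select_exposure

    cfg = scenarios.tzd_recovery(n_patients=12_000, seed=17, true_rr=1.2)
    cfg = cfg.replace(**NO_EFFECTS)
    tables = simulate(cfg)
    seg = build_tzd_segments(tables)
    s = attribute_events(seg, death_event_table(tables["patients"]),
                         incident_only=False, terminal=True)
    sel = select_exposure(s, CURRENT_LEVELS, reference="pioglitazone")
    cells = aggregate(sel, ["exposure"]).set_index("exposure")
    rr = (cells.loc["rosiglitazone", "events"] / cells.loc["rosiglitazone", "person_years"]) / (
        cells.loc["pioglitazone", "events"] / cells.loc["pioglitazone", "person_years"])
    se_log = np.sqrt(1 / cells.loc["rosiglitazone", "events"]
                     + 1 / cells.loc["pioglitazone", "events"])
    assert abs(np.log(rr) - np.log(1.2)) < 3 * se_log


class TestAnachronisms:
    def test_records_inside_observation_windows(self, small_tables):
        patients = small_tables["patients"].set_index("patient_id")
        for name in ("prescriptions", "events", "covariates"):
            df = small_tables[name]
            start = df["patient_id"].map(patients["data_start"])
            end = df["patient_id"].map(patients["data_end"])
            death = df["patient_id"].map(patients["death_day"]).astype("float64")
            assert (df["day"] >= start).all(), name
            assert (df["day"] < end).all(), name
            alive_limit = np.fmin(end, np.where(np.isnan(death), np.inf,
                                                death + 1))
            assert (df["day"] < alive_limit).all(), name
        assert (patients["death_day"].dropna()
                <= patients.loc[patients["death_day"].notna(), "data_end"]).all()

    def test_hospital_records_only_linked_in_window(self, small_tables,
                                                    small_config):
        patients = small_tables["patients"].set_index("patient_id")
        hosp = small_tables["events"].query("source == 'hospital'")
        assert hosp["patient_id"].map(patients["linked"]).all()
        assert (hosp["day"] >= to_day(small_config.hospital_window_start)).all()

    def test_death_certificates_only_linked_after_window_start(
            self, small_tables, small_config):
        """Certificate causes exist only for linked-practice deaths on or
        after the death-certificate collection start."""
        patients = small_tables["patients"].set_index("patient_id")
        causes = small_tables["death_causes"]
        assert causes["patient_id"].map(patients["linked"]).all()
        death_days = causes["patient_id"].map(patients["death_day"])
        assert (death_days >= to_day(small_config.death_cert_start)).all()
        # and every certificate death is flagged as such on the patient
        src = causes["patient_id"].map(patients["death_source"])
        assert src.str.contains("death-certificate").all()

    def test_certificate_flag_matches_linkage_and_window(self, small_tables,
                                                         small_config):
        patients = small_tables["patients"]
        dead = patients[patients["death_day"].notna()]
        expect = dead["linked"] & (
            dead["death_day"].astype("int64")
            >= to_day(small_config.death_cert_start))
        assert (dead["death_source"].str.contains("death-certificate")
                == expect).all()


def test_ground_truth_sidecar_completeness(small_tables):
    gt = small_tables["ground_truth"]
    for col in ("latent_severity", "n_comorbidities", "death_day",
                "event_exp_death", "init_exp_rosiglitazone"):
        assert col in gt.columns
    assert len(gt) == len(small_tables["patients"])
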
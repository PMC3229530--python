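"""Scenario configuration for the synthetic primary-care record generator.

A :class:`ScenarioConfig` fully determines a synthetic study population:
given the same config and seed the generator emits byte-identical
tables.  The defaults emulate a UK primary-care population of type-2
diabetic adults during 1998-2010: practice-clustered enrolment,
drug-class initiation with calendar trends (rosiglitazone initiation
collapsing after 2007, pioglitazone rising), channeling of sicker
patients towards insulin, repeat prescriptions sustaining exposure, and
partial hospital/death-certificate linkage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

DRUG_CLASSES = (
    "metformin",
    "sulphonylurea",
    "rosiglitazone",
    "pioglitazone",
    "insulin",
    "other_oad",
)

OUTCOMES = ("death", "acs", "stroke", "heart_failure")

COMORBIDITY_FLAGS = (
    "chd",
    "revascularisation",
    "hyperlipidaemia",
    "hypertension",
    "peripheral_vascular_disease",
    "renal_impairment",
    "stable_angina",
)

COMEDICATION_FLAGS = (
    "arb_acei",
    "antiplatelets",
    "beta_blockers",
    "calcium_channel_blockers",
    "diuretics",
    "nitrates",
    "nsaids_aspirin",
    "statins",
)

LIFESTYLE_COVARIATES = ("smoking", "alcohol", "bmi_category")

ICD10_CHAPTER_LABELS = (
    "A00-B99",
    "C00-D89",
    "E00-E90",
    "F00-F99",
    "G00-G99",
    "I00-I99",
    "J00-J99",
    "K00-K93",
    "L00-L99",
    "M00-M99",
    "N00-N99",
    "V01-Y98",
)


class ConfigurationError(ValueError):
    """Raised when a scenario configuration is internally inconsistent."""


def _default_calendar_multipliers() -> dict:
    # Rosiglitazone initiation collapses after 2007 (regulatory warnings);
    # pioglitazone keeps rising.  Other classes are calendar-stable.
    return {
        "rosiglitazone": {
            1998: 0.0, 1999: 0.2, 2000: 0.6, 2001: 1.0, 2002: 1.3,
            2003: 1.6, 2004: 1.8, 2005: 1.9, 2006: 2.0, 2007: 1.1,
            2008: 0.2, 2009: 0.1, 2010: 0.05,
        },
        "pioglitazone": {
            1998: 0.0, 1999: 0.2, 2000: 0.4, 2001: 0.5, 2002: 0.6,
            2003: 0.6, 2004: 0.7, 2005: 0.7, 2006: 0.7, 2007: 1.2,
            2008: 2.0, 2009: 1.4, 2010: 1.2,
        },
    }


def _default_initiation_rates() -> dict:
    # Baseline first-ever initiation hazards per person-year.
    return {
        "metformin": 0.10,
        "sulphonylurea": 0.06,
        "rosiglitazone": 0.020,
        "pioglitazone": 0.018,
        "insulin": 0.020,
        "other_oad": 0.010,
    }


def _default_true_log_rr() -> dict:
    # Ground-truth causal log rate ratios during current use,
    # keyed class -> outcome.  Unlisted pairs are 0 (no effect).
    import math

    return {
        "rosiglitazone": {
            "death": math.log(1.2),
            "heart_failure": math.log(1.7),
        },
    }


def _default_outcome_hazards() -> dict:
    # Baseline hazards per person-year for a 65-year-old female with no
    # comorbidity, average severity; magnitudes give crude rates around
    # 1.7/100 py for death and sub-1/100 py for the cardiovascular
    # outcomes, as seen in thiazolidinedione users.
    return {
        "death": 0.015,
        "acs": 0.008,
        "stroke": 0.004,
        "heart_failure": 0.006,
    }


def _default_cause_mix() -> dict:
    # Multinomial over ICD-10 chapters for the primary cause of death;
    # "default" applies unless the decedent is current on a class with
    # its own mix.  Circulatory deaths dominate, as in type-2 diabetes.
    default = {
        "A00-B99": 0.02,
        "C00-D89": 0.24,
        "E00-E90": 0.07,
        "F00-F99": 0.01,
        "G00-G99": 0.01,
        "I00-I99": 0.40,
        "J00-J99": 0.10,
        "K00-K93": 0.06,
        "L00-L99": 0.01,
        "M00-M99": 0.01,
        "N00-N99": 0.02,
        "V01-Y98": 0.02,
        "unclassified": 0.03,
    }
    return {"default": default}


def _default_persistence() -> dict:
    # Discontinuation hazards per person-year of current use; insulin is
    # essentially never stopped once started.
    return {
        "metformin": 0.25,
        "sulphonylurea": 0.30,
        "rosiglitazone": 0.35,
        "pioglitazone": 0.35,
        "insulin": 0.05,
        "other_oad": 0.50,
    }


@dataclass
class ScenarioConfig:
    """All knobs of the synthetic-record generator.

    Rates are per person-year; dates are ISO strings; ``seed`` fixes
    every random draw.
    """

    n_patients: int = 20_000
    n_practices: int = 100
    calendar_start: str = "1998-01-01"
    calendar_end: str = "2011-01-01"

    # demographics
    age_mean: float = 64.0
    age_sd: float = 12.0
    age_min: float = 40.0
    sex_ratio_male: float = 0.56
    type1_fraction: float = 0.02
    observation_mean_years: float = 8.0
    observation_min_years: float = 1.0

    # prescribing
    class_initiation_rates: dict = field(default_factory=_default_initiation_rates)
    calendar_multipliers: dict = field(default_factory=_default_calendar_multipliers)
    channeling_strength: dict = field(
        default_factory=lambda: {"insulin": 0.8, "sulphonylurea": 0.3}
    )
    prescription_cycle_days: float = 60.0
    prescription_cycle_jitter: float = 0.2
    persistence: dict = field(default_factory=_default_persistence)
    multi_constituent_fraction: float = 0.08

    # outcomes
    true_log_rr: dict = field(default_factory=_default_true_log_rr)
    recent_past_log_rr: dict = field(default_factory=dict)
    outcome_baseline_hazards: dict = field(default_factory=_default_outcome_hazards)
    outcome_age_coef: dict = field(
        default_factory=lambda: {
            "death": 0.9, "acs": 0.5, "stroke": 0.7, "heart_failure": 0.8,
        }
    )
    outcome_male_coef: dict = field(
        default_factory=lambda: {
            "death": 0.15, "acs": 0.4, "stroke": 0.1, "heart_failure": 0.2,
        }
    )
    outcome_comorbidity_coef: float = 0.25
    outcome_severity_coef: dict = field(
        default_factory=lambda: {
            "death": 0.5, "acs": 0.3, "stroke": 0.3, "heart_failure": 0.4,
        }
    )

    # duration-dependent current-use effects: class -> outcome ->
    # {"cutoff_days": d, "early": log RR before d, "late": log RR after},
    # measured from the first-ever prescription of the class; overrides
    # true_log_rr for that (class, outcome) pair when present
    duration_effects: dict = field(default_factory=dict)

    # cause of death
    cause_of_death_mix: dict = field(default_factory=_default_cause_mix)

    # linkage
    linkage_fraction: float = 0.4
    hospital_window_start: str = "1997-04-01"
    death_cert_start: str = "2001-01-01"
    hospital_capture: float = 0.7

    # covariates
    covariate_missing_fraction: float = 0.08
    comorbidity_severity_coef: float = 0.8

    seed: int = 20110

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        if self.n_practices <= 0:
            raise ConfigurationError("n_practices must be positive")
        for name in ("sex_ratio_male", "type1_fraction", "linkage_fraction",
                     "hospital_capture", "covariate_missing_fraction",
                     "multi_constituent_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for cls, rate in self.class_initiation_rates.items():
            if cls not in DRUG_CLASSES:
                raise ConfigurationError(f"unknown drug class {cls!r}")
            if rate < 0:
                raise ConfigurationError(f"initiation rate for {cls} must be >= 0")
        for cls, years in self.calendar_multipliers.items():
            if cls not in DRUG_CLASSES:
                raise ConfigurationError(f"unknown drug class {cls!r}")
            for year, mult in years.items():
                if mult < 0:
                    raise ConfigurationError(
                        f"calendar multiplier for {cls} in {year} must be >= 0"
                    )
        for mapping, label in ((self.true_log_rr, "true_log_rr"),
                               (self.recent_past_log_rr, "recent_past_log_rr")):
            for cls, outcomes in mapping.items():
                if cls not in DRUG_CLASSES:
                    raise ConfigurationError(f"{label}: unknown drug class {cls!r}")
                for outcome in outcomes:
                    if outcome not in OUTCOMES:
                        raise ConfigurationError(
                            f"{label}: unknown outcome {outcome!r} for {cls}"
                        )
        for outcome, rate in self.outcome_baseline_hazards.items():
            if outcome not in OUTCOMES:
                raise ConfigurationError(f"unknown outcome {outcome!r}")
            if rate < 0:
                raise ConfigurationError(f"baseline hazard for {outcome} must be >= 0")
        for cls, rate in self.persistence.items():
            if rate < 0:
                raise ConfigurationError(f"persistence hazard for {cls} must be >= 0")
        for cls, outcomes in self.duration_effects.items():
            if cls not in DRUG_CLASSES:
                raise ConfigurationError(f"duration_effects: unknown class {cls!r}")
            for outcome, spec in outcomes.items():
                if outcome not in OUTCOMES:
                    raise ConfigurationError(
                        f"duration_effects: unknown outcome {outcome!r}")
                if spec.get("cutoff_days", 0) <= 0:
                    raise ConfigurationError(
                        "duration_effects cutoff_days must be positive")
        for key, mix in self.cause_of_death_mix.items():
            if key != "default" and key not in DRUG_CLASSES:
                raise ConfigurationError(f"cause-of-death mix: unknown key {key!r}")
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-6:
                raise ConfigurationError(
                    f"cause-of-death mix {key!r} must sum to 1, got {total}"
                )

    # ------------------------------------------------------------------
    def current_log_rr(self, drug_class: str, outcome: str) -> float:
        return float(self.true_log_rr.get(drug_class, {}).get(outcome, 0.0))

    def recent_past_effect(self, drug_class: str, outcome: str) -> float:
        return float(self.recent_past_log_rr.get(drug_class, {}).get(outcome, 0.0))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def replace(self, **kwargs) -> "ScenarioConfig":
        return dataclasses.replace(self, **kwargs)
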
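"""Predefined study scenarios with known ground truth.

Each function returns a :class:`ScenarioConfig` tailored to one
question the pipeline must answer correctly:

* :func:`tzd_recovery` — no confounding, a known current-use death RR
  for rosiglitazone vs pioglitazone: the adjusted estimate must recover
  the truth and its CI must cover it at the nominal rate;
* :func:`bias_channeling` — sicker patients are channelled to insulin
  and severity drives death but is hidden from the models: the
  past-insulin negative-control RR must be elevated crude and
  attenuate, without vanishing, after adjustment;
* :func:`bias_null` — no channeling, no severity effect: past-use RRs
  must be compatible with 1;
* :func:`early_excess` — rosiglitazone's death RR is 2.0 early in
  treatment and 1.2 later: the smoothed duration-hazard ratio must
  peak in the first part of follow-up;
* :func:`cause_mix_shift` — equal all-cause mortality but a higher
  circulatory share for rosiglitazone: chapter RRs must separate while
  the all-cause RR stays near 1.

The thiazolidinedione initiation rates here are deliberately high and
calendar-flat so modest population sizes yield well-populated rosi/pio
inception cohorts; everything else keeps the default generator
conditions.
"""

from __future__ import annotations

import math

from .config import ScenarioConfig

#: flat initiation rates concentrating the population on the
#: rosiglitazone/pioglitazone contrast
_TZD_FOCUS_RATES = {
    "metformin": 0.12,
    "sulphonylurea": 0.05,
    "rosiglitazone": 0.12,
    "pioglitazone": 0.12,
    "insulin": 0.015,
    "other_oad": 0.005,
}

_NO_SEVERITY = {"death": 0.0, "acs": 0.0, "stroke": 0.0, "heart_failure": 0.0}


def tzd_recovery(n_patients: int = 4000, seed: int = 0,
                 true_rr: float = 1.2) -> ScenarioConfig:
    """Known current-use death RR, channeling off, severity inert."""
    return ScenarioConfig(
        n_patients=n_patients,
        n_practices=max(10, n_patients // 100),
        class_initiation_rates=dict(_TZD_FOCUS_RATES),
        calendar_multipliers={},
        channeling_strength={},
        outcome_severity_coef=dict(_NO_SEVERITY),
        true_log_rr={"rosiglitazone": {"death": math.log(true_rr)}},
        persistence={"metformin": 0.25, "sulphonylurea": 0.30,
                     "rosiglitazone": 0.25, "pioglitazone": 0.25,
                     "insulin": 0.05, "other_oad": 0.50},
        seed=seed,
    )


def bias_channeling(n_patients: int = 6000, seed: int = 0,
                    channeling: float = 1.0,
                    severity_death: float = 0.6) -> ScenarioConfig:
    """Confounding by severity: channelled insulin, hidden severity,
    no true drug effect on any outcome."""
    return ScenarioConfig(
        n_patients=n_patients,
        n_practices=max(10, n_patients // 100),
        class_initiation_rates={
            "metformin": 0.15, "sulphonylurea": 0.05,
            "rosiglitazone": 0.02, "pioglitazone": 0.02,
            "insulin": 0.06, "other_oad": 0.005,
        },
        calendar_multipliers={},
        channeling_strength={"insulin": channeling},
        outcome_severity_coef={"death": severity_death, "acs": 0.3,
                               "stroke": 0.3, "heart_failure": 0.4},
        true_log_rr={},
        seed=seed,
    )


def bias_null(n_patients: int = 6000, seed: int = 0) -> ScenarioConfig:
    """No channeling, severity inert, no drug effects: every past-use
    contrast should be compatible with 1."""
    cfg = bias_channeling(n_patients=n_patients, seed=seed, channeling=0.0,
                          severity_death=0.0)
    return cfg.replace(outcome_severity_coef=dict(_NO_SEVERITY))


def early_excess(n_patients: int = 4000, seed: int = 0,
                 cutoff_days: int = 365,
                 early_rr: float = 2.0, late_rr: float = 1.2) -> ScenarioConfig:
    """Rosiglitazone death RR high shortly after start, lower later.

    The default cutoff (one year) spans roughly the first tenth of the
    observed current-use durations under these persistence settings.
    """
    cfg = tzd_recovery(n_patients=n_patients, seed=seed)
    return cfg.replace(
        true_log_rr={},
        duration_effects={"rosiglitazone": {"death": {
            "cutoff_days": cutoff_days,
            "early": math.log(early_rr),
            "late": math.log(late_rr),
        }}},
        # a higher baseline death hazard keeps the per-period event
        # counts informative on the 100-period duration grid
        outcome_baseline_hazards={"death": 0.04, "acs": 0.008,
                                  "stroke": 0.004, "heart_failure": 0.006},
    )


def cause_mix_shift(n_patients: int = 8000, seed: int = 0,
                    rosi_circulatory: float = 0.40,
                    pio_circulatory: float = 0.30) -> ScenarioConfig:
    """Equal all-cause mortality, shifted circulatory share of deaths."""
    def mix(circ: float) -> dict:
        rest = {
            "A00-B99": 0.02, "C00-D89": 0.24, "E00-E90": 0.07,
            "F00-F99": 0.01, "G00-G99": 0.01, "J00-J99": 0.10,
            "K00-K93": 0.06, "L00-L99": 0.01, "M00-M99": 0.01,
            "N00-N99": 0.02, "V01-Y98": 0.02, "unclassified": 0.03,
        }
        scale = (1.0 - circ) / sum(rest.values())
        out = {k: v * scale for k, v in rest.items()}
        out["I00-I99"] = circ
        return out

    cfg = tzd_recovery(n_patients=n_patients, seed=seed)
    return cfg.replace(
        true_log_rr={},
        linkage_fraction=1.0,
        # a raised death hazard keeps the chapter-level counts
        # informative at desk-scale population sizes
        outcome_baseline_hazards={"death": 0.05, "acs": 0.008,
                                  "stroke": 0.004, "heart_failure": 0.006},
        cause_of_death_mix={
            "default": mix(pio_circulatory),
            "rosiglitazone": mix(rosi_circulatory),
            "pioglitazone": mix(pio_circulatory),
        },
    )
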
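"""Inception cohorts, the overall exposed cohort, and matched controls.

Cohort entry rules follow the new-user design: the index date of the
overall exposed cohort is the first prescription for insulin or any
oral antidiabetic at least one year (365 days) after the start of the
patient's data collection; an inception cohort for a drug class admits
a patient only if their *first-ever* prescription of that class falls
at least one year after data start (prior prescriptions of *other*
classes do not exclude, so patients can belong to multiple inception
cohorts — part of the guard against immortal time bias).

All date comparisons use half-open conventions; "one year after" means
``index >= data_start + 365`` (boundary inclusive).  Follow-up runs from
the index date to the censor date = min(end of data collection, day
after death), so a death day itself lies inside the half-open follow-up
interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DRUG_CLASSES, ConfigurationError
from .exposure_history import expand_prescriptions
from .timeutils import RUN_IN_DAYS, age_at


class ReferentialIntegrityError(ValueError):
    """Prescriptions or events reference patients absent from the table."""


@dataclass
class MatchCriteria:
    """Control-matching rules: same sex and practice, age within tolerance."""

    age_tolerance: float = 5.0
    match_on: tuple = ("sex", "practice")
    same_index_date: bool = True

    def __post_init__(self):
        if self.age_tolerance < 0:
            raise ConfigurationError("age_tolerance must be >= 0")


def _censor_day(patients: pd.DataFrame) -> pd.Series:
    death = patients["death_day"]
    censor = patients["data_end"].astype("float64").copy()
    has = death.notna()
    censor[has] = np.fmin(censor[has], death[has].astype("float64") + 1)
    return censor.astype("int64")


def _check_referential(patients: pd.DataFrame, prescriptions: pd.DataFrame):
    known = set(patients["patient_id"])
    unknown = set(prescriptions["patient_id"]) - known
    if unknown:
        raise ReferentialIntegrityError(
            f"{len(unknown)} prescription patient id(s) not in patient table"
        )


def build_exposed_cohort(patients: pd.DataFrame, prescriptions: pd.DataFrame,
                         min_age: float = 40.0) -> pd.DataFrame:
    """Prevalent-user cohort of all insulin/OAD-treated adults.

    One entry per qualifying patient; the index is the first diabetes
    prescription dated at least 365 days after data start and at age
    >= ``min_age``.  Earlier prescriptions are ignored for the index but
    remain in the exposure history.  Type-1 diabetic patients are
    excluded.
    """
    _check_referential(patients, prescriptions)
    rx = expand_prescriptions(prescriptions)
    pat = patients.set_index("patient_id")
    rx = rx.merge(
        patients[["patient_id", "birth_year", "data_start", "type1"]],
        on="patient_id",
    )
    rx["age"] = age_at(rx["day"].to_numpy(), rx["birth_year"].to_numpy())
    ok = (
        (rx["day"] >= rx["data_start"] + RUN_IN_DAYS)
        & (rx["age"] >= min_age)
        & ~rx["type1"]
    )
    idx = rx[ok].groupby("patient_id")["day"].min()
    censor = _censor_day(patients).set_axis(patients["patient_id"])
    out = pd.DataFrame({
        "patient_id": idx.index,
        "cohort": "overall-exposed",
        "index_day": idx.to_numpy(),
        "censor_day": censor.loc[idx.index].to_numpy(),
        "matched_to": pd.array([pd.NA] * len(idx), dtype="Int64"),
    })
    out = out[out["index_day"] < out["censor_day"]]
    return out.reset_index(drop=True)


def build_inception_cohort(patients: pd.DataFrame, prescriptions: pd.DataFrame,
                           drug_class: str, min_age: float = 40.0) -> pd.DataFrame:
    """New-user cohort for one drug class.

    Entry requires the patient's first-ever prescription of the class to
    fall at least 365 days after data start (boundary inclusive) at age
    >= ``min_age``; first-ever use of *other* classes inside the first
    year does not exclude.
    """
    if drug_class not in DRUG_CLASSES:
        raise ConfigurationError(f"unknown drug class {drug_class!r}")
    _check_referential(patients, prescriptions)
    rx = expand_prescriptions(prescriptions)
    first = rx[rx["drug_class"] == drug_class].groupby("patient_id")["day"].min()
    info = patients.set_index("patient_id").loc[first.index]
    age = age_at(first.to_numpy(), info["birth_year"].to_numpy())
    ok = (
        (first.to_numpy() >= info["data_start"].to_numpy() + RUN_IN_DAYS)
        & (age >= min_age)
        & ~info["type1"].to_numpy()
    )
    first = first[ok]
    censor = _censor_day(patients).set_axis(patients["patient_id"])
    out = pd.DataFrame({
        "patient_id": first.index,
        "cohort": f"inception:{drug_class}",
        "index_day": first.to_numpy(),
        "censor_day": censor.loc[first.index].to_numpy(),
        "matched_to": pd.array([pd.NA] * len(first), dtype="Int64"),
    })
    out = out[out["index_day"] < out["censor_day"]]
    return out.reset_index(drop=True)


def match_controls(exposed: pd.DataFrame, patients: pd.DataFrame,
                   prescriptions: pd.DataFrame,
                   criteria: MatchCriteria | None = None,
                   seed: int = 0):
    """Match each exposed patient to one diabetes-free control.

    Candidates have no diabetes prescription before the exposed
    patient's index date, are under observation on that date, share sex
    and practice, and are within ``age_tolerance`` years of age; the
    nearest-age candidate wins, ties broken by a seeded draw.  A control
    serves at most one exposed patient.  A control may later start
    diabetes treatment (and even enter an exposed cohort of their own);
    their control follow-up is censored at that first prescription.
    Restricting the pool to the never-treated instead would select
    against patients who survive long enough to be prescribed, biasing
    control mortality upward.

    Returns ``(controls, exposed)`` — the control cohort entries (with
    ``matched_to`` set) and a copy of ``exposed`` with a boolean
    ``matched`` column; unmatched exposed are flagged, not dropped.
    """
    criteria = criteria or MatchCriteria()
    rng = np.random.default_rng(seed)
    rx = expand_prescriptions(prescriptions)
    first_rx = rx.groupby("patient_id")["day"].min()

    pat = patients.copy()
    pat["first_rx"] = pat["patient_id"].map(first_rx)
    pat["censor"] = _censor_day(patients)

    exposed = exposed.copy()
    exposed["matched"] = False
    control_rows = []
    used: set = set()

    exp_info = exposed.merge(
        patients[["patient_id", "practice_id", "sex", "birth_year"]],
        on="patient_id",
    ).sort_values("patient_id")
    for practice, exp_grp in exp_info.groupby("practice_id", sort=True):
        pool = pat[pat["practice_id"] == practice]
        if pool.empty:
            continue
        p_id = pool["patient_id"].to_numpy()
        p_sex = pool["sex"].to_numpy()
        p_by = pool["birth_year"].to_numpy()
        p_start = pool["data_start"].to_numpy()
        p_cens = pool["censor"].to_numpy()
        p_first = pool["first_rx"].to_numpy(dtype="float64")

        for _, e in exp_grp.iterrows():
            index_day = int(e["index_day"])
            cand_age = age_at(np.full(len(p_id), index_day), p_by)
            exp_age = age_at(np.array([index_day]),
                             np.array([e["birth_year"]]))[0]
            mask = (
                (p_id != e["patient_id"])
                & (p_sex == e["sex"])
                & (p_start <= index_day)
                & (p_cens > index_day)
                & (np.isnan(p_first) | (p_first >= index_day))
                & (np.abs(cand_age - exp_age) <= criteria.age_tolerance)
            )
            avail = np.flatnonzero(mask)
            avail = avail[[p_id[i] not in used for i in avail]]
            if len(avail) == 0:
                continue
            diffs = np.abs(cand_age[avail] - exp_age)
            best = avail[diffs == diffs.min()]
            pick = int(best[rng.integers(len(best))]) if len(best) > 1 else int(best[0])
            cid = int(p_id[pick])
            used.add(cid)
            exposed.loc[exposed["patient_id"] == e["patient_id"], "matched"] = True
            ctrl_censor = p_cens[pick]
            if not np.isnan(p_first[pick]):
                ctrl_censor = min(ctrl_censor, int(p_first[pick]))
            control_rows.append((cid, "control", index_day, int(ctrl_censor),
                                 int(e["patient_id"])))

    controls = pd.DataFrame(
        control_rows,
        columns=["patient_id", "cohort", "index_day", "censor_day", "matched_to"],
    )
    if not controls.empty:
        controls = controls[controls["index_day"] < controls["censor_day"]]
        controls["matched_to"] = controls["matched_to"].astype("Int64")
    return controls.reset_index(drop=True), exposed
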
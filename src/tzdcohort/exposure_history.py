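"""Time-dependent drug-exposure classification and person-time splitting.

Prescription streams are converted into disjoint person-time segments
labelled, for every drug class, with one of four exposure states:

* ``current`` — within 3 months (91 days) of a prescription; overlapping
  windows from repeat prescriptions merge, so a repeat extends current use;
* ``recent``  — 3 to 12 months (91-365 days) after the most recent
  prescription;
* ``past``    — 12 months or more after the most recent prescription;
* ``never``   — no prescription of the class so far.

All intervals are half-open ``[start, end)`` on the integer-day axis.
Follow-up is partitioned at every state-change day of every class,
every calendar-year boundary, every age-band boundary and every
covariate-change day, so each segment is homogeneous in exposure and
covariates.  Because a class's person-time can only be labelled
``current`` from its first prescription onwards, time before treatment
start is never attributed to the treated state — the construction that
prevents immortal time bias.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import COMEDICATION_FLAGS, DRUG_CLASSES
from .timeutils import (
    COMED_LOOKBACK_DAYS,
    CURRENT_WINDOW_DAYS,
    RECENT_WINDOW_DAYS,
    age_at,
    day_to_year,
    mid_year_birthday,
    year_start_day,
)

logger = logging.getLogger(__name__)

STATES = ("never", "current", "recent", "past")

#: ages at which the modelling age band changes (10-year bands, 85+ top)
AGE_BAND_EDGES = (50, 60, 65, 70, 80, 85)


def expand_prescriptions(prescriptions: pd.DataFrame) -> pd.DataFrame:
    """Long-format (patient_id, day, drug_class) prescription stream.

    Multi-constituent preparations contribute one row per constituent
    class, so the patient enters both class histories on that date.
    """
    base = prescriptions[["patient_id", "day", "drug_class"]]
    if "multi_constituent" in prescriptions.columns:
        extra = prescriptions.loc[
            prescriptions["multi_constituent"].fillna("").ne(""),
            ["patient_id", "day", "multi_constituent"],
        ].rename(columns={"multi_constituent": "drug_class"})
        base = pd.concat([base, extra], ignore_index=True)
    return base.drop_duplicates().sort_values(["patient_id", "day"], kind="stable")


def classify_exposure(rx_days, query_day: int) -> str:
    """Exposure state of one patient-class history at ``query_day``.

    ``rx_days`` need not be sorted or unique.  The state depends only on
    the most recent prescription on or before the query day; merged
    current windows fall out of this rule automatically.
    """
    rx = np.unique(np.asarray(rx_days, dtype="int64"))
    if rx.size == 0:
        return "never"
    i = np.searchsorted(rx, query_day, side="right")
    if i == 0:
        return "never"
    dt = query_day - rx[i - 1]
    if dt < CURRENT_WINDOW_DAYS:
        return "current"
    if dt < RECENT_WINDOW_DAYS:
        return "recent"
    return "past"


def state_change_days(rx_days) -> np.ndarray:
    """Candidate days on which the exposure state can change.

    For each prescription at day *r* the state can change at *r*
    (to current), *r* + 91 (to recent) and *r* + 365 (to past); changes
    pre-empted by a later prescription are harmless duplicates.
    """
    rx = np.unique(np.asarray(rx_days, dtype="int64"))
    return np.unique(
        np.concatenate([rx, rx + CURRENT_WINDOW_DAYS, rx + RECENT_WINDOW_DAYS])
    )


def _states_at(rx_long: pd.DataFrame, drug_class: str,
               keys: pd.DataFrame) -> pd.Series:
    """Vectorised state of ``drug_class`` at (patient_id, start) rows."""
    rx = rx_long.loc[rx_long["drug_class"] == drug_class,
                     ["patient_id", "day"]].sort_values("day", kind="stable")
    if rx.empty:
        return pd.Series("never", index=keys["_row"].to_numpy())
    merged = pd.merge_asof(
        keys.sort_values("start", kind="stable"),
        rx.rename(columns={"day": "last_rx"}),
        left_on="start", right_on="last_rx",
        by="patient_id", direction="backward",
    ).set_index("_row").sort_index()
    dt = merged["start"] - merged["last_rx"]
    state = pd.Series("never", index=merged.index, dtype="object")
    state[dt >= RECENT_WINDOW_DAYS] = "past"
    state[dt < RECENT_WINDOW_DAYS] = "recent"
    state[dt < CURRENT_WINDOW_DAYS] = "current"
    state[merged["last_rx"].isna()] = "never"
    return state


def first_rx_day(prescriptions: pd.DataFrame, drug_class: str) -> pd.Series:
    """First-ever prescription day of ``drug_class`` per patient."""
    rx = expand_prescriptions(prescriptions)
    rx = rx[rx["drug_class"] == drug_class]
    return rx.groupby("patient_id")["day"].min()


def split_person_time(
    cohort: pd.DataFrame,
    prescriptions: pd.DataFrame,
    patients: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    reference_class: str | None = None,
    classes=DRUG_CLASSES,
) -> pd.DataFrame:
    """Partition each cohort member's follow-up into labelled segments.

    Parameters
    ----------
    cohort
        One row per member with ``patient_id``, ``index_day``,
        ``censor_day``.
    prescriptions
        Prescription table (``patient_id``, ``day``, ``drug_class``,
        optional ``multi_constituent``); unordered input is sorted, and
        duplicate prescriptions are idempotent.
    patients
        Patient table with ``birth_year`` (for age bands).
    covariates
        Optional long table (``patient_id``, ``day``, ``covariate``,
        ``value``); each segment carries the most recent value before
        its start.  Co-medication covariates use a 183-day lookback.
    reference_class
        If given, follow-up is additionally censored at the first
        prescription of this class (active-comparator censoring).

    Returns
    -------
    DataFrame with one row per segment: ``patient_id``, ``start``,
    ``end``, ``duration``, one ``state_<class>`` column per class,
    ``age_years``, ``age_band``, ``calendar_year`` and one column per
    covariate name.  Segments tile ``[index_day, censor_day)`` exactly.
    """
    cohort = cohort[["patient_id", "index_day", "censor_day"]].copy()
    rx_long = expand_prescriptions(prescriptions)
    rx_long = rx_long[rx_long["patient_id"].isin(cohort["patient_id"])]

    if reference_class is not None:
        if reference_class not in DRUG_CLASSES:
            raise ValueError(f"unknown reference class {reference_class!r}")
        ref_first = first_rx_day(prescriptions, reference_class)
        capped = cohort["patient_id"].map(ref_first)
        cohort["censor_day"] = np.fmin(cohort["censor_day"], capped)

    cohort = cohort[cohort["index_day"] < cohort["censor_day"]]
    if cohort.empty:
        return _empty_segments(classes, covariates)

    pat_cols = ["patient_id", "birth_year"]
    for extra in ("sex", "linked"):
        if extra in patients.columns:
            pat_cols.append(extra)
    info = cohort.merge(patients[pat_cols], on="patient_id", how="left")

    cuts = [cohort[["patient_id"]].assign(day=cohort["index_day"])]

    # exposure-state changes for every class of interest
    rx_members = rx_long[rx_long["drug_class"].isin(classes)]
    if not rx_members.empty:
        days = rx_members["day"].to_numpy()
        pats = rx_members["patient_id"].to_numpy()
        cuts.append(pd.DataFrame({
            "patient_id": np.tile(pats, 3),
            "day": np.concatenate([
                days, days + CURRENT_WINDOW_DAYS, days + RECENT_WINDOW_DAYS
            ]),
        }))

    # calendar-year boundaries
    years = np.arange(
        int(day_to_year(int(cohort["index_day"].min()))),
        int(day_to_year(int(cohort["censor_day"].max() - 1))) + 1,
    )
    for year in years[1:]:
        cuts.append(cohort[["patient_id"]].assign(day=year_start_day(int(year))))

    # age-band boundaries (July-1 birthday convention)
    for edge in AGE_BAND_EDGES:
        cuts.append(pd.DataFrame({
            "patient_id": info["patient_id"],
            "day": mid_year_birthday(info["birth_year"].to_numpy(), edge),
        }))

    if covariates is not None and not covariates.empty:
        cov = covariates[covariates["patient_id"].isin(cohort["patient_id"])]
        cuts.append(cov[["patient_id", "day"]])
        # a co-medication record stops counting 183 days after issue
        comed = cov[cov["covariate"].isin(COMEDICATION_FLAGS)]
        if not comed.empty:
            cuts.append(pd.DataFrame({
                "patient_id": comed["patient_id"],
                "day": comed["day"] + COMED_LOOKBACK_DAYS,
            }))

    cut = pd.concat(cuts, ignore_index=True)
    cut = cut.merge(cohort, on="patient_id")
    cut = cut[(cut["day"] >= cut["index_day"]) & (cut["day"] < cut["censor_day"])]
    cut = cut[["patient_id", "day", "censor_day"]].drop_duplicates(
        ["patient_id", "day"]
    ).sort_values(["patient_id", "day"], kind="stable")

    seg = cut.rename(columns={"day": "start"})
    nxt = seg.groupby("patient_id")["start"].shift(-1)
    seg["end"] = nxt.fillna(seg["censor_day"]).astype("int64")
    seg = seg.drop(columns="censor_day").reset_index(drop=True)
    seg["duration"] = seg["end"] - seg["start"]

    seg["_row"] = np.arange(len(seg))
    keys = seg[["_row", "patient_id", "start"]]
    for cls in classes:
        seg[f"state_{cls}"] = _states_at(rx_long, cls, keys).to_numpy()

    pinfo = info.drop_duplicates("patient_id").set_index("patient_id")
    birth = seg["patient_id"].map(pinfo["birth_year"]).to_numpy()
    seg["age_years"] = age_at(seg["start"].to_numpy(), birth)
    seg["age_band"] = age_band(seg["age_years"])
    seg["calendar_year"] = day_to_year(seg["start"].to_numpy())
    for extra in ("sex", "linked"):
        if extra in pinfo.columns:
            seg[extra] = seg["patient_id"].map(pinfo[extra]).to_numpy()

    if covariates is not None and not covariates.empty:
        seg = _snapshot_covariates(seg, covariates)
    seg = seg.drop(columns="_row")
    return seg


def age_band(ages) -> pd.Series:
    """Modelling age bands: 40-49, 50-59, 60-64, 65-69, 70-79, 80-84, 85+."""
    edges = [-np.inf, *AGE_BAND_EDGES, np.inf]
    labels = ["40-49", "50-59", "60-64", "65-69", "70-79", "80-84", "85+"]
    return pd.cut(np.asarray(ages), bins=edges, labels=labels, right=False).astype(str)


def _snapshot_covariates(seg: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    cov = covariates[covariates["patient_id"].isin(seg["patient_id"].unique())]
    keys = seg[["_row", "patient_id", "start"]]
    for name, group in cov.groupby("covariate"):
        g = group[["patient_id", "day", "value"]].sort_values("day", kind="stable")
        merged = pd.merge_asof(
            keys.sort_values("start", kind="stable"), g,
            left_on="start", right_on="day",
            by="patient_id", direction="backward",
        ).set_index("_row").sort_index()
        value = merged["value"]
        if name in COMEDICATION_FLAGS:
            stale = (merged["start"] - merged["day"]) >= COMED_LOOKBACK_DAYS
            value = value.where(~stale)
        seg[name] = value.fillna("none").to_numpy()
    return seg


def _empty_segments(classes, covariates) -> pd.DataFrame:
    cols = ["patient_id", "start", "end", "duration"]
    cols += [f"state_{c}" for c in classes]
    cols += ["age_years", "age_band", "calendar_year"]
    if covariates is not None and not covariates.empty:
        cols += sorted(covariates["covariate"].unique())
    return pd.DataFrame(columns=cols)


def attribute_events(
    segments: pd.DataFrame,
    events: pd.DataFrame,
    incident_only: bool = True,
    terminal: bool = False,
) -> pd.DataFrame:
    """Attach first-event counts to person-time segments.

    ``events`` needs ``patient_id`` and ``day`` (already filtered to one
    outcome and source).  Each patient's first event is counted in the
    unique segment whose half-open interval contains it; an event on a
    segment boundary belongs to the segment beginning that day.  Later
    events of the same outcome are dropped.  With ``incident_only``,
    patients with a record of the outcome before their index date
    contribute no person-time at all.  With ``terminal`` (deaths), the
    segment containing the event is truncated to end the day after the
    event and any later segments are removed.

    Returns a copy of ``segments`` with an integer ``events`` column.
    """
    seg = segments.copy()
    seg["events"] = 0
    if seg.empty or events is None or events.empty:
        return seg

    index_day = seg.groupby("patient_id")["start"].min()
    censor_day = seg.groupby("patient_id")["end"].max()

    ev = events[events["patient_id"].isin(index_day.index)]
    first_any = ev.groupby("patient_id")["day"].min()
    if incident_only:
        pre = first_any.index[first_any < index_day.loc[first_any.index]]
        if len(pre):
            seg = seg[~seg["patient_id"].isin(pre)].copy()
            ev = ev[~ev["patient_id"].isin(pre)]

    in_followup = (
        (ev["day"] >= ev["patient_id"].map(index_day))
        & (ev["day"] < ev["patient_id"].map(censor_day))
    )
    n_outside = int((~in_followup).sum())
    if n_outside:
        logger.warning("%d event(s) outside follow-up ignored", n_outside)
    first = ev[in_followup].groupby("patient_id")["day"].min()
    if first.empty:
        return seg.reset_index(drop=True)

    ev = first.rename("event_day").reset_index()
    seg = seg.merge(ev, on="patient_id", how="left")
    hit = (seg["event_day"] >= seg["start"]) & (seg["event_day"] < seg["end"])
    seg.loc[hit, "events"] = 1
    if terminal:
        seg.loc[hit, "end"] = seg.loc[hit, "event_day"] + 1
        after = seg["event_day"].notna() & (seg["start"] > seg["event_day"])
        seg = seg[~after].copy()
        seg["duration"] = seg["end"] - seg["start"]
    seg = seg.drop(columns="event_day").reset_index(drop=True)
    return seg


def assert_no_immortal_time(segments: pd.DataFrame,
                            prescriptions: pd.DataFrame) -> None:
    """Raise if any segment is labelled current before the class's first Rx."""
    rx_long = expand_prescriptions(prescriptions)
    for cls in [c.removeprefix("state_") for c in segments.columns
                if c.startswith("state_")]:
        col = f"state_{cls}"
        cur = segments.loc[segments[col] == "current", ["patient_id", "start"]]
        if cur.empty:
            continue
        firsts = rx_long[rx_long["drug_class"] == cls].groupby("patient_id")["day"].min()
        f = cur["patient_id"].map(firsts)
        bad = f.isna() | (cur["start"] < f)
        if bad.any():
            raise AssertionError(
                f"immortal time: {int(bad.sum())} current-{cls} segment(s) "
                "precede the first prescription"
            )
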
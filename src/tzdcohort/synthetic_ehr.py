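"""Synthetic primary-care record generator with known ground truth.

Emits the five record tables the analysis pipeline consumes — patients,
prescriptions, clinical events, death causes and covariates — plus a
ground-truth sidecar holding every latent draw (severity, unit
exponential variates) needed to recompute any patient's hazard
trajectory exactly.

The generative model:

* patients aged >=40 (truncated normal), clustered in practices, a
  configurable fraction of which are linked to hospital and
  death-certificate data;
* a latent standard-normal *severity* score per patient enters both
  drug-initiation hazards (channeling of sicker patients to insulin)
  and outcome hazards log-linearly — the confounding-by-severity
  mechanism the bias analysis must detect;
* drug-class initiation follows piecewise-constant hazards over
  calendar years (rosiglitazone initiation collapses after 2007);
  repeat prescriptions every ``prescription_cycle_days`` sustain
  exposure until an exponentially distributed discontinuation;
* outcome events are drawn from competing piecewise-constant hazards
  with exact inversion per constant piece (no discretisation error):
  baseline x exp(age, sex, comorbidity, severity terms) x
  exp(true log RR of each currently used class);
* deaths in linked practices after the death-certificate window start
  get a primary cause drawn from a per-class multinomial over ICD-10
  chapters; hospital event records exist only for linked practices
  within the hospital-data window.

Exposure-state timing is imported from :mod:`tzdcohort.exposure_history`
so the generator and the analysis use one set of window rules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    COMEDICATION_FLAGS,
    COMORBIDITY_FLAGS,
    DRUG_CLASSES,
    OUTCOMES,
    ConfigurationError,
    ScenarioConfig,
)
from .exposure_history import first_rx_day, split_person_time
from .timeutils import PERSON_YEAR_DAYS, day_to_year, to_day, year_start_day

#: representative ICD-10 codes per chapter (weights sum to 1 within chapter)
SAMPLE_ICD10 = {
    "A00-B99": [("A41.9", 0.7), ("B18.1", 0.3)],
    "C00-D89": [("C34.9", 0.35), ("C50.9", 0.2), ("C61", 0.2), ("D64.9", 0.25)],
    "E00-E90": [("E11.9", 0.7), ("E14.1", 0.3)],
    "F00-F99": [("F03", 0.8), ("F10.2", 0.2)],
    "G00-G99": [("G30.9", 0.6), ("G20", 0.4)],
    "I00-I99": [
        ("I21.9", 0.34), ("I25.1", 0.24), ("I50.0", 0.18),
        ("I63.9", 0.12), ("I10", 0.06), ("I71.3", 0.06),
    ],
    "J00-J99": [("J18.9", 0.55), ("J44.9", 0.45)],
    "K00-K93": [("K92.2", 0.5), ("K70.3", 0.5)],
    "L00-L99": [("L03.9", 1.0)],
    "M00-M99": [("M06.9", 1.0)],
    "N00-N99": [("N18.9", 0.6), ("N39.0", 0.4)],
    "V01-Y98": [("W19", 0.5), ("X59.9", 0.5)],
    "unclassified": [("", 1.0)],
}

#: when a decedent is current on several classes, the cause-of-death mix
#: of the first class in this order that has its own mix applies
CAUSE_MIX_PRIORITY = (
    "rosiglitazone", "pioglitazone", "insulin",
    "sulphonylurea", "metformin", "other_oad",
)

_COMORBIDITY_BASE = {
    "chd": 0.11, "revascularisation": 0.04, "hyperlipidaemia": 0.10,
    "hypertension": 0.70, "peripheral_vascular_disease": 0.05,
    "renal_impairment": 0.04, "stable_angina": 0.13,
}

_COMEDICATION_BASE = {
    "arb_acei": 0.45, "antiplatelets": 0.38, "beta_blockers": 0.24,
    "calcium_channel_blockers": 0.25, "diuretics": 0.35, "nitrates": 0.10,
    "nsaids_aspirin": 0.45, "statins": 0.50,
}

_SMOKING = (("non", 0.41), ("ex", 0.40), ("current", 0.19))
_ALCOHOL = (("no", 0.35), ("yes", 0.65))
_BMI = (("<25", 0.18), ("25-30", 0.35), ("30+", 0.47))


def _streams(seed: int, names) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


# ----------------------------------------------------------------------
# population
# ----------------------------------------------------------------------

def generate_population(config: ScenarioConfig, rng=None):
    """Draw the patient table and the ground-truth sidecar.

    Returns ``(patients, ground_truth)``.  Death columns are filled in
    later by :func:`generate_outcomes`.
    """
    config.validate()
    if rng is None:
        rng = _streams(config.seed, ["population"])["population"]
    n = config.n_patients

    practice_id = rng.integers(1, config.n_practices + 1, size=n)
    linked_practices = rng.random(config.n_practices) < config.linkage_fraction
    linked = linked_practices[practice_id - 1]

    sex = np.where(rng.random(n) < config.sex_ratio_male, "M", "F")
    a = (config.age_min - config.age_mean) / config.age_sd
    age0 = stats.truncnorm.rvs(
        a, np.inf, loc=config.age_mean, scale=config.age_sd,
        size=n, random_state=rng,
    )

    cal_start = to_day(config.calendar_start)
    cal_end = to_day(config.calendar_end)
    min_obs = int(config.observation_min_years * 365)
    latest_start = max(cal_start + 1, cal_end - min_obs)
    data_start = rng.integers(cal_start, latest_start, size=n)
    extra = rng.exponential(
        max(config.observation_mean_years - config.observation_min_years, 0.01)
        * PERSON_YEAR_DAYS, size=n,
    )
    data_end = np.minimum(data_start + min_obs + extra.astype("int64"), cal_end)

    birth_year = day_to_year(data_start) - np.round(age0).astype("int64")
    type1 = rng.random(n) < config.type1_fraction
    severity = rng.standard_normal(n)

    patients = pd.DataFrame({
        "patient_id": np.arange(1, n + 1),
        "practice_id": practice_id,
        "linked": linked,
        "sex": sex,
        "birth_year": birth_year,
        "data_start": data_start.astype("int64"),
        "data_end": data_end.astype("int64"),
        "death_day": pd.array([pd.NA] * n, dtype="Int64"),
        "death_source": "",
        "type1": type1,
    })
    ground_truth = pd.DataFrame({
        "patient_id": patients["patient_id"],
        "latent_severity": severity,
    })
    return patients, ground_truth


# ----------------------------------------------------------------------
# covariates
# ----------------------------------------------------------------------

def generate_covariates(patients: pd.DataFrame, ground_truth: pd.DataFrame,
                        config: ScenarioConfig, rng=None) -> pd.DataFrame:
    """Baseline comorbidity/lifestyle records plus recurring co-medication.

    Comorbidity flags load on latent severity, so severity is partially
    observable through them.  A configurable fraction of
    smoking/alcohol/BMI values is absent to exercise missing-category
    handling.  Co-medication records repeat every 182 days while in use
    (just inside the analysis's 6-month lookback).
    """
    if rng is None:
        rng = _streams(config.seed, ["population", "covariates"])["covariates"]
    n = len(patients)
    sev = ground_truth.set_index("patient_id").loc[
        patients["patient_id"], "latent_severity"
    ].to_numpy()
    pid = patients["patient_id"].to_numpy()
    start = patients["data_start"].to_numpy()
    end = patients["data_end"].to_numpy()

    rows = []

    for flag in COMORBIDITY_FLAGS:
        p = _expit(_logit(_COMORBIDITY_BASE[flag])
                   + config.comorbidity_severity_coef * sev)
        has = rng.random(n) < p
        rows.append(pd.DataFrame({
            "patient_id": pid[has], "day": start[has],
            "covariate": flag, "value": "yes",
        }))

    def categorical(name, levels):
        labels = [v for v, _ in levels]
        probs = np.array([w for _, w in levels])
        vals = rng.choice(labels, size=n, p=probs / probs.sum())
        present = rng.random(n) >= config.covariate_missing_fraction
        return pd.DataFrame({
            "patient_id": pid[present], "day": start[present],
            "covariate": name, "value": vals[present],
        })

    rows.append(categorical("smoking", _SMOKING))
    rows.append(categorical("alcohol", _ALCOHOL))
    rows.append(categorical("bmi_category", _BMI))

    ses = rng.integers(1, 6, size=n)
    rows.append(pd.DataFrame({
        "patient_id": pid, "day": start, "covariate": "ses_quintile",
        "value": ses.astype(str),
    }))

    for med in COMEDICATION_FLAGS:
        p = _expit(_logit(_COMEDICATION_BASE[med]) + 0.4 * sev)
        user = rng.random(n) < p
        if not user.any():
            continue
        u_pid, u_start, u_end = pid[user], start[user], end[user]
        counts = np.maximum(-(-(u_end - u_start) // 182), 1)
        rep_pid = np.repeat(u_pid, counts)
        offsets = np.concatenate([np.arange(c) for c in counts]) * 182
        rep_day = np.repeat(u_start, counts) + offsets
        rows.append(pd.DataFrame({
            "patient_id": rep_pid, "day": rep_day,
            "covariate": med, "value": "yes",
        }))

    cov = pd.concat(rows, ignore_index=True)
    return cov.sort_values(["patient_id", "covariate", "day"],
                           kind="stable").reset_index(drop=True)


# ----------------------------------------------------------------------
# piecewise-constant hazard inversion
# ----------------------------------------------------------------------

def piecewise_exponential_day(pieces: pd.DataFrame, rate_col: str,
                              exp_draw: pd.Series) -> pd.Series:
    """First-event day from piecewise-constant hazards, by exact inversion.

    ``pieces`` has ``patient_id``, ``start``, ``end`` (half-open days,
    sorted within patient) and a per-person-year rate column; ``exp_draw``
    maps patient_id to a unit-exponential variate.  Returns the integer
    event day for patients whose cumulative hazard reaches the draw
    before their pieces run out (others are absent from the result).
    """
    if pieces.empty:
        return pd.Series(dtype="int64")
    rate_day = pieces[rate_col].to_numpy() / PERSON_YEAR_DAYS
    length = (pieces["end"] - pieces["start"]).to_numpy()
    haz = rate_day * length
    cum_end = pd.Series(haz).groupby(
        pieces["patient_id"].to_numpy()).cumsum().to_numpy()
    cum_start = cum_end - haz
    e = pieces["patient_id"].map(exp_draw).to_numpy()
    hit = (e > cum_start) & (e <= cum_end) & (rate_day > 0)
    t = pieces["start"].to_numpy()[hit] + (e[hit] - cum_start[hit]) / rate_day[hit]
    day = np.minimum(np.floor(t).astype("int64"),
                     pieces["end"].to_numpy()[hit] - 1)
    return pd.Series(day, index=pieces["patient_id"].to_numpy()[hit])


def _year_pieces(patients: pd.DataFrame) -> pd.DataFrame:
    """Observation windows cut at calendar-year boundaries (long format)."""
    start = patients["data_start"].to_numpy()
    end = patients["data_end"].to_numpy()
    y0 = int(day_to_year(start.min()))
    y1 = int(day_to_year(end.max() - 1))
    frames = []
    for year in range(y0, y1 + 1):
        ys, ye = year_start_day(year), year_start_day(year + 1)
        s = np.maximum(start, ys)
        e = np.minimum(end, ye)
        keep = s < e
        frames.append(pd.DataFrame({
            "patient_id": patients["patient_id"].to_numpy()[keep],
            "start": s[keep], "end": e[keep], "year": year,
        }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["patient_id", "start"],
                           kind="stable").reset_index(drop=True)


# ----------------------------------------------------------------------
# prescriptions
# ----------------------------------------------------------------------

def generate_prescriptions(patients: pd.DataFrame, config: ScenarioConfig,
                           ground_truth: pd.DataFrame, rng=None):
    """Draw initiation times and repeat prescriptions for every class.

    Returns ``(prescriptions, summary, ground_truth)`` where ``summary``
    counts initiations by class and calendar year and the sidecar gains
    the initiation exponential draws and episode ends.
    """
    if rng is None:
        rng = _streams(config.seed,
                       ["population", "covariates", "prescriptions"])["prescriptions"]
    sev = ground_truth.set_index("patient_id")["latent_severity"]
    pieces = _year_pieces(patients)
    sev_piece = pieces["patient_id"].map(sev).to_numpy()
    data_end = patients.set_index("patient_id")["data_end"]

    cycle = config.prescription_cycle_days
    jitter = config.prescription_cycle_jitter
    frames = []
    gt = ground_truth.copy()

    for cls in DRUG_CLASSES:
        base = config.class_initiation_rates.get(cls, 0.0)
        mults = config.calendar_multipliers.get(cls, {})
        chan = config.channeling_strength.get(cls, 0.0)

        mult = pieces["year"].map(lambda y: mults.get(int(y), 1.0)).to_numpy()
        rate = base * mult * np.exp(chan * sev_piece)
        pieces["_rate"] = rate
        e = pd.Series(rng.exponential(size=len(patients)),
                      index=patients["patient_id"].to_numpy())
        gt[f"init_exp_{cls}"] = e.loc[gt["patient_id"]].to_numpy()
        t0 = piecewise_exponential_day(pieces, "_rate", e)
        if t0.empty:
            gt[f"episode_end_{cls}"] = np.nan
            continue

        pers = config.persistence.get(cls, 0.3)
        if pers > 0:
            dur = rng.exponential(PERSON_YEAR_DAYS / pers, size=len(t0))
        else:
            dur = np.full(len(t0), np.inf)
        stop = np.minimum(t0.to_numpy() + dur,
                          data_end.loc[t0.index].to_numpy())
        span = stop - t0.to_numpy()
        max_k = int(np.ceil(span.max() / (cycle * (1 - jitter)))) + 1
        max_k = min(max_k, 400)
        intervals = rng.uniform(1 - jitter, 1 + jitter,
                                size=(len(t0), max_k)) * cycle
        offsets = np.concatenate(
            [np.zeros((len(t0), 1)), np.cumsum(intervals, axis=1)], axis=1
        )
        days = t0.to_numpy()[:, None] + np.round(offsets).astype("int64")
        keep = days < stop[:, None]
        pid_rep = np.repeat(t0.index.to_numpy(), keep.sum(axis=1))
        day_rep = days[keep]

        multi = np.full(len(t0), "", dtype=object)
        if cls in ("rosiglitazone", "pioglitazone"):
            combo = rng.random(len(t0)) < config.multi_constituent_fraction
            multi[combo] = "metformin"
        multi_rep = np.repeat(multi, keep.sum(axis=1))

        frames.append(pd.DataFrame({
            "patient_id": pid_rep, "day": day_rep, "drug_class": cls,
            "multi_constituent": multi_rep,
        }))
        ep = pd.Series(stop, index=t0.index)
        gt[f"episode_end_{cls}"] = gt["patient_id"].map(ep)

    pieces.drop(columns="_rate", inplace=True, errors="ignore")
    if frames:
        prescriptions = pd.concat(frames, ignore_index=True)
        prescriptions = prescriptions.sort_values(
            ["patient_id", "day", "drug_class"], kind="stable"
        ).reset_index(drop=True)
    else:
        prescriptions = pd.DataFrame(
            columns=["patient_id", "day", "drug_class", "multi_constituent"]
        )

    if prescriptions.empty:
        summary = pd.DataFrame(columns=["drug_class", "year", "initiations"])
    else:
        firsts = prescriptions.groupby(
            ["patient_id", "drug_class"], as_index=False)["day"].min()
        firsts["year"] = day_to_year(firsts["day"].to_numpy())
        summary = (firsts.groupby(["drug_class", "year"]).size()
                   .rename("initiations").reset_index())
    return prescriptions, summary, gt


# ----------------------------------------------------------------------
# outcomes
# ----------------------------------------------------------------------

def generate_outcomes(patients: pd.DataFrame, prescriptions: pd.DataFrame,
                      config: ScenarioConfig, ground_truth: pd.DataFrame,
                      covariates: pd.DataFrame | None = None, rng=None):
    """Draw outcome events, deaths and death causes.

    Hazard pieces follow the exposure segments produced by
    :func:`tzdcohort.exposure_history.split_person_time` over each
    patient's full observation window, so the generator's notion of
    current/recent/past use is identical to the analysis's.

    Returns ``(events, death_causes, patients, ground_truth)`` with
    death day/source filled in on the patient table.
    """
    for cls, outcomes in config.true_log_rr.items():
        for outcome in outcomes:
            if cls not in DRUG_CLASSES or outcome not in OUTCOMES:
                raise ConfigurationError(
                    f"unknown (class, outcome) pair ({cls!r}, {outcome!r})"
                )
    if rng is None:
        rng = _streams(
            config.seed,
            ["population", "covariates", "prescriptions", "outcomes"],
        )["outcomes"]

    obs = pd.DataFrame({
        "patient_id": patients["patient_id"],
        "index_day": patients["data_start"],
        "censor_day": patients["data_end"],
    })
    seg = split_person_time(obs, prescriptions, patients, covariates=None)

    # duration-dependent effects need hazard pieces cut at each
    # patient's first-Rx-plus-cutoff day
    duration_cuts = {}
    for cls, outcomes in config.duration_effects.items():
        first = first_rx_day(prescriptions, cls)
        for outcome, spec in outcomes.items():
            cut = first + spec["cutoff_days"]
            duration_cuts[(cls, outcome)] = cut
            seg = _split_at_patient_days(seg, cut)

    sev = ground_truth.set_index("patient_id")["latent_severity"]
    male = patients.set_index("patient_id")["sex"].eq("M")
    if covariates is not None and not covariates.empty:
        ncom = (covariates[covariates["covariate"].isin(COMORBIDITY_FLAGS)]
                .groupby("patient_id").size())
    else:
        ncom = pd.Series(dtype="int64")

    seg_sev = seg["patient_id"].map(sev).fillna(0.0).to_numpy()
    seg_male = seg["patient_id"].map(male).fillna(False).to_numpy()
    seg_ncom = seg["patient_id"].map(ncom).fillna(0).to_numpy()
    seg_age = seg["age_years"].to_numpy()

    gt = ground_truth.copy()
    gt["n_comorbidities"] = gt["patient_id"].map(ncom).fillna(0).astype(int)

    event_days = {}
    for outcome in OUTCOMES:
        base = config.outcome_baseline_hazards.get(outcome, 0.0)
        log_rate = np.full(len(seg), -np.inf if base == 0 else np.log(base))
        if base > 0:
            log_rate = log_rate + (
                config.outcome_age_coef.get(outcome, 0.0) * (seg_age - 65) / 10.0
                + config.outcome_male_coef.get(outcome, 0.0) * seg_male
                + config.outcome_comorbidity_coef * seg_ncom
                + config.outcome_severity_coef.get(outcome, 0.0) * seg_sev
            )
            for cls in DRUG_CLASSES:
                lrr = config.current_log_rr(cls, outcome)
                rp = config.recent_past_effect(cls, outcome)
                state = seg[f"state_{cls}"].to_numpy()
                de = config.duration_effects.get(cls, {}).get(outcome)
                if de is not None:
                    cut = seg["patient_id"].map(
                        duration_cuts[(cls, outcome)]).to_numpy()
                    current = state == "current"
                    early = current & (seg["start"].to_numpy() < cut)
                    late = current & ~early
                    log_rate = log_rate + de["early"] * early + de["late"] * late
                elif lrr != 0.0:
                    log_rate = log_rate + lrr * (state == "current")
                if rp != 0.0:
                    log_rate = log_rate + rp * np.isin(state, ("recent", "past"))
        seg["_rate"] = np.where(np.isfinite(log_rate), np.exp(log_rate), 0.0)
        e = pd.Series(rng.exponential(size=len(patients)),
                      index=patients["patient_id"].to_numpy())
        gt[f"event_exp_{outcome}"] = e.loc[gt["patient_id"]].to_numpy()
        event_days[outcome] = piecewise_exponential_day(seg, "_rate", e)
    seg.drop(columns="_rate", inplace=True, errors="ignore")

    death = event_days["death"]
    pats = patients.copy().set_index("patient_id")
    pats.loc[death.index, "death_day"] = death.to_numpy()
    linked = pats["linked"]
    cert_start = to_day(config.death_cert_start)
    has_cert = linked.loc[death.index].to_numpy() & (death.to_numpy() >= cert_start)
    src = np.where(has_cert, "gp+death-certificate", "gp")
    pats.loc[death.index, "death_source"] = src
    pats = pats.reset_index()

    gt["death_day"] = gt["patient_id"].map(death)

    # nonfatal events, censored at death
    hosp_start = to_day(config.hospital_window_start)
    frames = []
    for outcome in OUTCOMES:
        if outcome == "death":
            continue
        days = event_days[outcome]
        if days.empty:
            continue
        d = death.reindex(days.index)
        keep = d.isna() | (days <= d)
        days = days[keep]
        pid = days.index.to_numpy()
        frames.append(pd.DataFrame({
            "patient_id": pid, "day": days.to_numpy(),
            "outcome": outcome, "source": "gp",
        }))
        lk = linked.loc[pid].to_numpy()
        in_window = days.to_numpy() >= hosp_start
        captured = rng.random(len(days)) < config.hospital_capture
        hosp = lk & in_window & captured
        if hosp.any():
            frames.append(pd.DataFrame({
                "patient_id": pid[hosp], "day": days.to_numpy()[hosp],
                "outcome": outcome, "source": "hospital",
            }))
    if frames:
        events = pd.concat(frames, ignore_index=True).sort_values(
            ["patient_id", "day", "outcome", "source"], kind="stable"
        ).reset_index(drop=True)
    else:
        events = pd.DataFrame(columns=["patient_id", "day", "outcome", "source"])

    death_causes = _draw_death_causes(seg, death, has_cert, config, rng)
    return events, death_causes, pats, gt


def _draw_death_causes(seg, death, has_cert, config, rng) -> pd.DataFrame:
    cert_pids = death.index.to_numpy()[has_cert]
    cert_days = death.to_numpy()[has_cert]
    if len(cert_pids) == 0:
        return pd.DataFrame(columns=["patient_id", "icd10_code", "chapter"])

    # exposure state at death from the generator's own segment grid
    at_death = pd.merge_asof(
        pd.DataFrame({"patient_id": cert_pids, "day": cert_days})
        .sort_values("day", kind="stable"),
        seg[["patient_id", "start"] + [f"state_{c}" for c in CAUSE_MIX_PRIORITY]]
        .sort_values("start", kind="stable"),
        left_on="day", right_on="start", by="patient_id", direction="backward",
    )

    mixes = config.cause_of_death_mix
    rows = []
    for _, row in at_death.iterrows():
        mix_key = "default"
        for cls in CAUSE_MIX_PRIORITY:
            if cls in mixes and row.get(f"state_{cls}") == "current":
                mix_key = cls
                break
        mix = mixes.get(mix_key, mixes["default"])
        chapters = list(mix.keys())
        probs = np.array([mix[c] for c in chapters])
        chapter = rng.choice(chapters, p=probs / probs.sum())
        codes = SAMPLE_ICD10.get(chapter, [("", 1.0)])
        labels = [c for c, _ in codes]
        w = np.array([p for _, p in codes])
        code = rng.choice(labels, p=w / w.sum())
        rows.append((row["patient_id"], code, chapter))
    return pd.DataFrame(rows, columns=["patient_id", "icd10_code", "chapter"])


def _split_at_patient_days(seg: pd.DataFrame, cut: pd.Series) -> pd.DataFrame:
    """Split each patient's straddling segment at a per-patient day."""
    c = seg["patient_id"].map(cut)
    hit = c.notna() & (seg["start"] < c) & (seg["end"] > c)
    if not hit.any():
        return seg
    left = seg[hit].copy()
    right = seg[hit].copy()
    left["end"] = c[hit].astype("int64")
    right["start"] = c[hit].astype("int64")
    out = pd.concat([seg[~hit], left, right], ignore_index=True)
    out["duration"] = out["end"] - out["start"]
    return out.sort_values(["patient_id", "start"],
                           kind="stable").reset_index(drop=True)


# ----------------------------------------------------------------------
# orchestration
# ----------------------------------------------------------------------

def simulate(config: ScenarioConfig, out_dir=None, seed: int | None = None) -> dict:
    """Run the full generator; optionally write the tables and manifest.

    Returns a dict of tables: ``patients``, ``prescriptions``,
    ``events``, ``death_causes``, ``covariates``, ``ground_truth`` and
    the initiation ``summary``.  Identical config and seed give
    identical tables.
    """
    if seed is not None:
        config = config.replace(seed=seed)
    rngs = _streams(config.seed,
                    ["population", "covariates", "prescriptions", "outcomes"])
    patients, gt = generate_population(config, rngs["population"])
    covariates = generate_covariates(patients, gt, config, rngs["covariates"])
    prescriptions, summary, gt = generate_prescriptions(
        patients, config, gt, rngs["prescriptions"])
    events, death_causes, patients, gt = generate_outcomes(
        patients, prescriptions, config, gt, covariates, rngs["outcomes"])

    # records never extend beyond death
    death = patients.set_index("patient_id")["death_day"]
    for name, df in (("prescriptions", prescriptions), ("covariates", covariates)):
        d = df["patient_id"].map(death)
        keep = d.isna() | (df["day"] <= d)
        if name == "prescriptions":
            prescriptions = df[keep].reset_index(drop=True)
        else:
            covariates = df[keep].reset_index(drop=True)

    tables = {
        "patients": patients,
        "prescriptions": prescriptions,
        "events": events,
        "death_causes": death_causes[["patient_id", "icd10_code"]],
        "covariates": covariates,
        "ground_truth": gt,
    }
    if out_dir is not None:
        from pathlib import Path

        import yaml

        from .io import write_tables

        write_tables(tables, out_dir)
        summary.to_csv(Path(out_dir) / "initiation_summary.csv", index=False)
        manifest = {"config": config.to_dict(), "seed": config.seed}
        with open(Path(out_dir) / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    tables["summary"] = summary
    return tables
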
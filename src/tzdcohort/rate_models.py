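"""Incidence rates and log-linear (Poisson) rate models.

Person-time segments are aggregated into cells cross-classified by the
exposure term and the adjustment covariates; a Poisson model with a log
person-time offset is maximised over the cells.  By Poisson
sufficiency the cell-level fit is identical to a segment-level fit, so
aggregation is purely a computational device.

The minimal adjustment set is age band, sex and calendar year; the full
set adds lifestyle covariates (smoking, alcohol, BMI, with missing
values as their own category), comorbidity history flags, recent
co-medication, the socioeconomic quintile (only in analyses restricted
to linked practices) and current-use indicators of the other diabetes
drug classes.  Confidence intervals are Wald intervals on the log
scale, exp(beta +/- 1.96 se).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import (
    COMEDICATION_FLAGS,
    COMORBIDITY_FLAGS,
    DRUG_CLASSES,
    LIFESTYLE_COVARIATES,
)
from .timeutils import PERSON_YEAR_DAYS, year_start_day

Z95 = 1.959963984540054

MINIMAL_ADJUSTMENT = ("age_band", "sex", "calendar_year")

#: a |log RR| or its SE beyond this marks a (quasi-)separated level
SEPARATION_SE = 10.0
SEPARATION_COEF = 10.0


class DomainError(ValueError):
    """Invalid value domain (e.g. non-positive person-time)."""


class ConvergenceError(RuntimeError):
    """The iteratively reweighted least squares fit did not converge."""


def incidence_rate(events: float, person_years: float) -> float:
    """Events per 100 person-years."""
    if person_years <= 0:
        raise DomainError("person_years must be positive")
    return 100.0 * events / person_years


def person_years(duration_days) -> float:
    return float(np.sum(duration_days)) / PERSON_YEAR_DAYS


def aggregate(segments: pd.DataFrame, by) -> pd.DataFrame:
    """Collapse segments into (events, person_years) cells."""
    by = list(by)
    g = segments.groupby(by, observed=True, dropna=False)
    out = g.agg(events=("events", "sum"),
                days=("duration", "sum")).reset_index()
    out["person_years"] = out["days"] / PERSON_YEAR_DAYS
    return out.drop(columns="days")


def select_exposure(segments: pd.DataFrame, levels: dict,
                    reference: str) -> pd.DataFrame:
    """Label segments with an exposure level and drop the rest.

    ``levels`` maps label -> (drug_class, state); a segment matching
    several levels takes the first match in the mapping's order.  The
    reference level must be one of the labels.
    """
    if reference not in levels:
        raise ValueError(f"reference {reference!r} not among exposure levels")
    seg = segments.copy()
    exposure = pd.Series(pd.NA, index=seg.index, dtype="object")
    for label, (cls, state) in levels.items():
        match = seg[f"state_{cls}"].eq(state) & exposure.isna()
        exposure[match] = label
    seg["exposure"] = exposure
    seg = seg[seg["exposure"].notna()].copy()
    return seg


@dataclass
class RateModelFit:
    """A fitted Poisson rate model.

    ``terms`` holds one row per coefficient (term, coef, se, rr, lcl,
    ucl, separated); ``exposure_table`` the crude events/person-years by
    exposure level; ``reference`` the reference exposure label.
    """

    terms: pd.DataFrame
    exposure_table: pd.DataFrame
    reference: str
    adjustment: tuple
    strata: str | None = None
    converged: bool = True
    n_cells: int = 0

    def rr(self, term: str) -> float:
        row = self.terms[self.terms["term"] == term]
        if row.empty:
            raise KeyError(term)
        return float(row["rr"].iloc[0])

    def ci(self, term: str):
        row = self.terms[self.terms["term"] == term]
        if row.empty:
            raise KeyError(term)
        return float(row["lcl"].iloc[0]), float(row["ucl"].iloc[0])

    def is_separated(self, term: str) -> bool:
        row = self.terms[self.terms["term"] == term]
        if row.empty:
            raise KeyError(term)
        return bool(row["separated"].iloc[0])


def _dummies(values: pd.Series, reference, prefix: str) -> pd.DataFrame:
    vals = values.astype(str)
    ref = str(reference)
    levels = [v for v in sorted(vals.unique()) if v != ref]
    out = pd.DataFrame(index=values.index)
    for lev in levels:
        out[f"{prefix}[{lev}]"] = (vals == lev).astype(float)
    return out


def _independent_columns(mat: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Greedy left-to-right selection of linearly independent columns.

    Earlier columns win, so the intercept and exposure terms are never
    the ones dropped when dummies are collinear.
    """
    n, p = mat.shape
    keep = np.zeros(p, dtype=bool)
    basis = np.empty((n, 0))
    for j in range(p):
        col = mat[:, j].astype(float)
        resid = col - basis @ (basis.T @ col)
        norm = np.linalg.norm(col)
        if norm > 0 and np.linalg.norm(resid) > tol * norm:
            keep[j] = True
            basis = np.concatenate([basis, (resid / np.linalg.norm(resid))[:, None]],
                                   axis=1)
    return keep


def full_adjustment_columns(segments: pd.DataFrame,
                            include_ses: bool = False) -> list:
    cols = list(MINIMAL_ADJUSTMENT)
    for name in (*LIFESTYLE_COVARIATES, *COMORBIDITY_FLAGS, *COMEDICATION_FLAGS):
        if name in segments.columns:
            cols.append(name)
    if include_ses and "ses_quintile" in segments.columns:
        cols.append("ses_quintile")
    return cols


def fit_rate_model(
    segments: pd.DataFrame,
    exposure: str = "exposure",
    reference: str | None = None,
    adjustment="minimal",
    include_ses: bool = False,
    other_class_current=(),
    strata_label: str | None = None,
) -> RateModelFit:
    """Fit a Poisson rate model with log person-time offset.

    ``segments`` must carry ``events`` and ``duration`` columns and the
    exposure column.  ``adjustment`` is ``"none"``, ``"minimal"``,
    ``"full"`` or an explicit list of categorical column names.
    ``other_class_current`` adds current-use indicator terms for the
    named drug classes (the paper-style mutual adjustment for
    co-prescribed diabetes medication).
    """
    if segments["events"].sum() < 1:
        raise DomainError("no events in data; rate model not estimable")
    if adjustment == "none":
        adj_cols: list = []
    elif adjustment == "minimal":
        adj_cols = list(MINIMAL_ADJUSTMENT)
    elif adjustment == "full":
        adj_cols = full_adjustment_columns(segments, include_ses=include_ses)
    else:
        adj_cols = list(adjustment)
    adj_cols = [c for c in adj_cols if c in segments.columns]

    seg = segments.copy()
    for cls in other_class_current:
        seg[f"current_{cls}"] = seg[f"state_{cls}"].eq("current").astype(int)
    extra = [f"current_{cls}" for cls in other_class_current]

    levels = seg[exposure].astype(str)
    if reference is None:
        reference = sorted(levels.unique())[0]

    cells = aggregate(seg, [exposure, *adj_cols, *extra])
    cells = cells[cells["person_years"] > 0].reset_index(drop=True)

    X = [pd.Series(1.0, index=cells.index, name="intercept")]
    X.append(_dummies(cells[exposure], reference, exposure))
    for col in adj_cols:
        ref_level = sorted(cells[col].astype(str).unique())[0]
        X.append(_dummies(cells[col], ref_level, col))
    for col in extra:
        X.append(cells[col].astype(float).rename(f"{col}[1]"))
    design = pd.concat(X, axis=1)
    # drop empty dummy columns (levels absent after aggregation)
    design = design.loc[:, (design != 0).any(axis=0)]
    # drop linearly dependent columns, keeping intercept and exposure
    # terms by priority (they come first)
    design = design.loc[:, _independent_columns(design.to_numpy())]

    model = sm.GLM(
        cells["events"].to_numpy(dtype=float),
        design.to_numpy(),
        family=sm.families.Poisson(),
        offset=np.log(cells["person_years"].to_numpy()),
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        res = model.fit(maxiter=200, tol=1e-10)
    if not getattr(res, "converged", True):
        # Under (quasi-)separation the offending parameters drift while
        # the deviance is flat; accept a flat-deviance fit (runaway
        # levels are flagged below via their standard errors) and raise
        # only when the likelihood is genuinely still improving.
        dev = getattr(res, "fit_history", {}).get("deviance", [])
        rel = (abs(dev[-1] - dev[-2]) / (abs(dev[-1]) + 1e-12)
               if len(dev) >= 2 and np.isfinite(dev[-1]) else np.inf)
        if not rel < 1e-5:
            raise ConvergenceError(
                "IRLS did not converge in 200 iterations; last deviance "
                f"values: {[float(d) for d in dev[-5:]]}"
            )

    coefs = pd.Series(res.params, index=design.columns)
    ses = pd.Series(res.bse, index=design.columns)
    separated = (ses > SEPARATION_SE) | (coefs.abs() > SEPARATION_COEF)
    terms = pd.DataFrame({
        "term": design.columns,
        "coef": coefs.to_numpy(),
        "se": ses.to_numpy(),
    })
    with np.errstate(over="ignore"):
        terms["rr"] = np.exp(terms["coef"])
        terms["lcl"] = np.exp(terms["coef"] - Z95 * terms["se"])
        terms["ucl"] = np.exp(terms["coef"] + Z95 * terms["se"])
    terms["separated"] = separated.to_numpy()
    terms.loc[terms["separated"], ["lcl", "ucl"]] = [0.0, np.inf]

    crude = aggregate(seg, [exposure])
    crude["rate_per_100py"] = 100 * crude["events"] / crude["person_years"]
    return RateModelFit(
        terms=terms,
        exposure_table=crude,
        reference=reference,
        adjustment=tuple(adj_cols),
        strata=strata_label,
        converged=True,
        n_cells=len(cells),
    )


def split_at_day(segments: pd.DataFrame, day: int) -> pd.DataFrame:
    """Divide any segment straddling ``day`` into two at that boundary.

    Covariate snapshots (taken at the original segment start) are
    carried into both halves.  An event in a straddling segment is kept
    in the right half: the pipeline only ever cuts at days that are
    already segment boundaries or, for terminal events, days no later
    than the event (a terminal segment ends the day after its event),
    so this convention never misplaces an event in practice.
    """
    seg = segments.copy()
    hit = (seg["start"] < day) & (seg["end"] > day)
    if not hit.any():
        return seg
    left = seg[hit].copy()
    right = seg[hit].copy()
    left["end"] = day
    left["events"] = 0  # an event day >= the cut belongs to the right half
    right["start"] = day
    out = pd.concat([seg[~hit], left, right], ignore_index=True)
    out["duration"] = out["end"] - out["start"]
    return out.sort_values(["patient_id", "start"],
                           kind="stable").reset_index(drop=True)


def run_stratified(segments: pd.DataFrame, strata: str, **fit_kwargs) -> dict:
    """Independent fits per stratum.

    ``strata`` is one of ``"age65"`` (age at segment start <65 / >=65),
    ``"insulin"`` (current insulin co-prescribing of the segment) or
    ``"calendar2007"`` (before/after 2007-01-01; segments straddling the
    boundary are divided first).  Empty or event-free strata are
    reported as ``"not-estimable"``.
    """
    if strata == "age65":
        groups = {"<65": segments[segments["age_years"] < 65],
                  ">=65": segments[segments["age_years"] >= 65]}
    elif strata == "insulin":
        cur = segments["state_insulin"].eq("current")
        groups = {"no": segments[~cur], "yes": segments[cur]}
    elif strata == "calendar2007":
        seg = split_at_day(segments, year_start_day(2007))
        before = seg["start"] < year_start_day(2007)
        groups = {"<2007": seg[before], ">=2007": seg[~before]}
    else:
        raise ValueError(f"unknown stratification {strata!r}")

    out = {}
    for label, grp in groups.items():
        if grp.empty or grp["events"].sum() < 1 or grp["exposure"].nunique() < 2:
            out[label] = "not-estimable"
            continue
        try:
            out[label] = fit_rate_model(grp, strata_label=f"{strata}={label}",
                                        **fit_kwargs)
        except (DomainError, ConvergenceError):
            out[label] = "not-estimable"
    return out
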
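"""Kaplan-Meier life tables, cumulative incidence and excess risk.

The product-limit estimator describes the absolute incidence of an
outcome over current use, accounting for loss to follow-up while not
adjusting for any risk factors.  Variance is Greenwood's formula;
confidence intervals for cumulative incidence use the log(-log)
transform, which keeps them inside [0, 100]%.  Excess risk between two
groups is the difference of their cumulative incidences at a common
horizon, computed at full precision and rounded only for display.

Ties are handled with events before censorings: a spell censored at
time *t* is still at risk for an event at *t*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timeutils import THREE_YEARS_DAYS, YEAR_DAYS

Z95 = 1.959963984540054

DEFAULT_HORIZONS = {"1y": YEAR_DAYS, "3y": THREE_YEARS_DAYS}


@dataclass
class LifeTable:
    """Product-limit estimates at the ordered distinct event times."""

    times: np.ndarray        # distinct event times, ascending
    at_risk: np.ndarray      # risk-set size just before each time
    events: np.ndarray       # events at each time
    survival: np.ndarray     # S(t) just after each time
    greenwood_var: np.ndarray  # Var-hat[S(t)]
    cum_greenwood: np.ndarray  # sum d/(n(n-d)) up to each time
    n_subjects: int

    def survival_at(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])

    def _cum_term_at(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if i < 0 else float(self.cum_greenwood[i])

    @property
    def max_time(self) -> float:
        return float(self.times[-1]) if len(self.times) else 0.0

    def cumulative_incidence(self) -> np.ndarray:
        """1 - S(t) as a percentage, per event time."""
        return 100.0 * (1.0 - self.survival)


def kaplan_meier(durations, observed) -> LifeTable:
    """Product-limit estimator from right-censored spells.

    ``durations`` are positive times from the start of current use;
    ``observed`` marks spells ending in the event.
    """
    dur = np.asarray(durations, dtype="float64")
    obs = np.asarray(observed, dtype=bool)
    if dur.size == 0:
        raise ValueError("no spells")
    if np.any(dur <= 0):
        raise ValueError("durations must be positive")

    times, d = np.unique(dur[obs], return_counts=True)
    if times.size == 0:
        return LifeTable(
            times=np.array([]), at_risk=np.array([]), events=np.array([]),
            survival=np.array([]), greenwood_var=np.array([]),
            cum_greenwood=np.array([]), n_subjects=dur.size,
        )
    sorted_dur = np.sort(dur)
    # risk set just before t: spells with duration >= t
    at_risk = dur.size - np.searchsorted(sorted_dur, times, side="left")
    d = d.astype("float64")
    frac = 1.0 - d / at_risk
    survival = np.cumprod(frac)
    cum = np.cumsum(d / (at_risk * (at_risk - d).clip(min=np.finfo(float).tiny)))
    var = survival ** 2 * cum
    return LifeTable(
        times=times, at_risk=at_risk.astype("int64"), events=d.astype("int64"),
        survival=survival, greenwood_var=var, cum_greenwood=cum,
        n_subjects=dur.size,
    )


def cumulative_incidence_at(table: LifeTable, horizon: float,
                            warn=None) -> dict:
    """Cumulative incidence % at ``horizon`` with a 95% log(-log) CI.

    If the horizon exceeds the last observed event time the last value
    is carried forward and ``extrapolated`` is flagged.
    """
    if table.n_subjects == 0:
        raise ValueError("empty life table")
    extrapolated = bool(len(table.times)) and horizon > table.max_time
    s = table.survival_at(horizon)
    ci_pct = 100.0 * (1.0 - s)
    if s <= 0.0 or s >= 1.0:
        lo, hi = ci_pct, ci_pct
    else:
        cum = table._cum_term_at(horizon)
        se_theta = np.sqrt(cum) / abs(np.log(s))
        bounds = s ** np.exp(np.array([-Z95, Z95]) * se_theta)
        lo = 100.0 * (1.0 - bounds.max())
        hi = 100.0 * (1.0 - bounds.min())
    return {
        "incidence_pct": ci_pct, "lcl": lo, "ucl": hi,
        "extrapolated": extrapolated,
    }


def excess_risk(a: float, b: float) -> float:
    """Difference of two cumulative incidences (%), full precision."""
    return a - b


def life_table_report(spells_by_group: dict, horizons=None) -> pd.DataFrame:
    """Cumulative incidence at each horizon per group, plus excess risks.

    ``spells_by_group`` maps group label to a spells DataFrame with
    ``duration`` and ``observed``.  Excess rows are the difference of
    the first group minus each other group, computed before rounding.
    """
    horizons = horizons or DEFAULT_HORIZONS
    rows = []
    tables = {}
    for label, spells in spells_by_group.items():
        if len(spells) == 0:
            continue
        tables[label] = kaplan_meier(spells["duration"], spells["observed"])
    for hname, hdays in horizons.items():
        for label, tab in tables.items():
            res = cumulative_incidence_at(tab, hdays)
            rows.append({
                "group": label, "horizon": hname,
                "incidence_pct": res["incidence_pct"],
                "lcl": res["lcl"], "ucl": res["ucl"],
                "n": tab.n_subjects,
                "extrapolated": res["extrapolated"],
            })
    report = pd.DataFrame(rows)
    if len(tables) >= 2:
        labels = list(tables)
        first = labels[0]
        excess = []
        for hname in horizons:
            base = report.query("group == @first and horizon == @hname")
            if base.empty:
                continue
            for other in labels[1:]:
                o = report.query("group == @other and horizon == @hname")
                if o.empty:
                    continue
                excess.append({
                    "group": f"{first} - {other}", "horizon": hname,
                    "incidence_pct": excess_risk(
                        float(base["incidence_pct"].iloc[0]),
                        float(o["incidence_pct"].iloc[0]),
                    ),
                    "lcl": np.nan, "ucl": np.nan,
                    "n": int(base["n"].iloc[0]) + int(o["n"].iloc[0]),
                    "extrapolated": bool(base["extrapolated"].iloc[0]
                                         or o["extrapolated"].iloc[0]),
                })
        report = pd.concat([report, pd.DataFrame(excess)], ignore_index=True)
    return report
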
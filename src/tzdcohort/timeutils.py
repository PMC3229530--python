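"""Calendar arithmetic on an integer-day axis.

All dates in the pipeline are integer days since a global epoch
(1990-01-01).  Working on an integer axis removes every calendar
ambiguity from window arithmetic: exposure windows, censoring rules and
person-time tiling are exact integer interval operations.

Conventions used throughout the package:

* intervals are half-open ``[start, end)``;
* "3 months" = 91 days, "12 months" = 365 days (exposure windows);
* "month" = 30.44 days where fractional month arithmetic is needed;
* 1 year = 365 days, 3 years = 1095 days (life-table horizons).
"""

from __future__ import annotations

import datetime as _dt

import numpy as np

EPOCH = _dt.date(1990, 1, 1)

#: current-use window: prescription date up to 3 months after
CURRENT_WINDOW_DAYS = 91
#: recent use ends 12 months after the most recent prescription
RECENT_WINDOW_DAYS = 365
#: days per month where month arithmetic is needed
DAYS_PER_MONTH = 30.44
#: eligibility run-in: index must fall at least one year after data start
RUN_IN_DAYS = 365
#: co-medication lookback (≈ 6 months)
COMED_LOOKBACK_DAYS = 183

YEAR_DAYS = 365
THREE_YEARS_DAYS = 1095
#: days per person-year when converting day counts to person-years
PERSON_YEAR_DAYS = 365.25


def to_day(date: "str | _dt.date | int") -> int:
    """Convert an ISO date string or :class:`datetime.date` to epoch days."""
    if isinstance(date, (int, np.integer)):
        return int(date)
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    return (date - EPOCH).days


def to_date(day: int) -> _dt.date:
    """Inverse of :func:`to_day`."""
    return EPOCH + _dt.timedelta(days=int(day))


def days_to_dates(days) -> np.ndarray:
    """Vectorised epoch-day -> ``datetime64[D]`` conversion."""
    return np.datetime64(EPOCH.isoformat(), "D") + np.asarray(days, dtype="int64")


def dates_to_days(dates) -> np.ndarray:
    """Vectorised date-like -> epoch-day conversion (accepts strings)."""
    arr = np.asarray(dates, dtype="datetime64[D]")
    return (arr - np.datetime64(EPOCH.isoformat(), "D")).astype("int64")


def year_start_day(year: int) -> int:
    """Epoch day of January 1 of ``year``."""
    return to_day(_dt.date(int(year), 1, 1))


def day_to_year(days) -> np.ndarray:
    """Calendar year containing each epoch day (vectorised)."""
    d = days_to_dates(days)
    return d.astype("datetime64[Y]").astype(int) + 1970


def mid_year_birthday(birth_year, target_age) -> np.ndarray:
    """Epoch day on which a person born in ``birth_year`` turns ``target_age``.

    Birth dates are anonymised to a year; ages are computed from a
    mid-year (July 1) birthday convention.
    """
    by = np.asarray(birth_year, dtype="int64")
    ta = np.asarray(target_age, dtype="int64")
    years = by + ta
    base = (years - 1970).astype("datetime64[Y]").astype("datetime64[D]")
    mid = base + np.timedelta64(181, "D")  # July 1 (day 182 of a non-leap year)
    return (mid - np.datetime64(EPOCH.isoformat(), "D")).astype("int64")


def age_at(day, birth_year) -> np.ndarray:
    """Completed age in years at ``day`` under the July-1 birthday rule."""
    day = np.asarray(day, dtype="int64")
    by = np.asarray(birth_year, dtype="int64")
    year = day_to_year(day)
    birthday_this_year = mid_year_birthday(by, year - by)
    age = year - by - 1 + (day >= birthday_this_year).astype("int64")
    return age
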
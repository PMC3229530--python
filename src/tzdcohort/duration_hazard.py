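"""Risk over duration of current use: 100-period grids and kernel-smoothed
hazards.

Follow-up during current use of a drug class is measured from the start
of the current-use spell (the inception prescription) and divided into
``n_periods`` equal-width periods spanning [0, longest observed
duration].  Within each period the raw hazard increment is the
Nelson-Aalen step d_i / Y_i, taken here with Y_i = (person-time in the
period) / (period width), i.e. the average number at risk.  The
smoothed hazard is the Ramlau-Hansen kernel estimator

    h(t) = (1/b) * sum_i K((t - t_i)/b) * dH_i

with the increments dH_i placed at period midpoints t_i, an
Epanechnikov kernel by default, and reflection at both boundaries so
the integral of the increments (the cumulative hazard at maximum
duration) is preserved up to kernel boundary error.  The comparison
curve between two drugs is the pointwise ratio of two separately
smoothed hazards, masked where the denominator falls below a floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exposure_history import expand_prescriptions
from .timeutils import CURRENT_WINDOW_DAYS


class EmptyGridError(ValueError):
    """No current-use spells to build a duration grid from."""


KERNELS = {
    "epanechnikov": lambda u: 0.75 * (1 - u ** 2) * (np.abs(u) <= 1),
    "uniform": lambda u: 0.5 * (np.abs(u) <= 1.0),
    "biweight": lambda u: (15 / 16) * (1 - u ** 2) ** 2 * (np.abs(u) <= 1),
}


@dataclass
class DurationGrid:
    """Equal-width duration periods with events and person-time at risk."""

    boundaries: np.ndarray  # length n_periods + 1, strictly increasing
    events: np.ndarray      # per-period event counts
    person_time: np.ndarray  # per-period time at risk (same units as durations)

    @property
    def n_periods(self) -> int:
        return len(self.events)

    @property
    def width(self) -> float:
        return float(self.boundaries[1] - self.boundaries[0])

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.boundaries[:-1] + self.boundaries[1:])

    def increments(self) -> np.ndarray:
        """Nelson-Aalen increments d_i / Y_i per period (0 where empty)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            y = self.person_time / self.width
            dh = np.where(y > 0, self.events / y, 0.0)
        return dh


@dataclass
class SmoothedHazard:
    """Kernel-smoothed hazard values on an evaluation grid."""

    times: np.ndarray
    values: np.ndarray
    bandwidth: float
    kernel: str


def current_use_spells(cohort: pd.DataFrame, prescriptions: pd.DataFrame,
                       drug_class: str,
                       events: pd.DataFrame | None = None) -> pd.DataFrame:
    """Time-to-event/censoring from the start of current use.

    A spell starts at the cohort index date (the inception
    prescription) and ends at the first of: exit from current use (91
    days after the last prescription of an unbroken repeat run), the
    censor date, or the event.  Returns one row per member with
    ``patient_id``, ``duration`` (days) and ``observed`` (event flag).
    """
    rx = expand_prescriptions(prescriptions)
    rx = rx[rx["drug_class"] == drug_class]
    rx = rx.merge(cohort[["patient_id", "index_day", "censor_day"]],
                  on="patient_id")
    rx = rx[rx["day"] >= rx["index_day"]].sort_values(
        ["patient_id", "day"], kind="stable")

    # end of the unbroken current-use run that starts at the index:
    # a gap > 91 days between consecutive prescriptions breaks the run
    gap = rx.groupby("patient_id")["day"].diff()
    broken = gap > CURRENT_WINDOW_DAYS
    run_break = broken.groupby(rx["patient_id"].to_numpy()).cummax()
    in_run = rx[~run_break.to_numpy().astype(bool)]
    run_last = in_run.groupby("patient_id")["day"].max()

    out = cohort[["patient_id", "index_day", "censor_day"]].copy()
    out["exit_day"] = out["patient_id"].map(run_last) + CURRENT_WINDOW_DAYS
    out = out[out["exit_day"].notna()]
    end = np.fmin(out["exit_day"], out["censor_day"])

    if events is not None and not events.empty:
        first = events.groupby("patient_id")["day"].min()
        ev_day = out["patient_id"].map(first)
    else:
        ev_day = pd.Series(np.nan, index=out.index)
    observed = ev_day.notna() & (ev_day >= out["index_day"]) & (ev_day < end)
    end = np.where(observed, ev_day + 1, end)

    out["duration"] = end - out["index_day"]
    out["observed"] = observed.to_numpy()
    out = out[out["duration"] > 0]
    return out[["patient_id", "duration", "observed"]].reset_index(drop=True)


def build_duration_grid(durations, observed, n_periods: int = 100,
                        max_duration: float | None = None) -> DurationGrid:
    """Equal-width duration grid with per-period events and person-time.

    ``durations`` are spell lengths from the start of current use;
    ``observed`` flags spells ending in the event.  Person-time in
    period [a, b) is the summed overlap of [0, duration) with [a, b);
    an event is counted in the period containing the spell's endpoint
    (events exactly on the top boundary fall in the last period).
    ``max_duration`` pins the grid span (e.g. to share one grid between
    two drugs); default is the longest spell.
    """
    dur = np.asarray(durations, dtype="float64")
    obs = np.asarray(observed, dtype=bool)
    if dur.size == 0:
        raise EmptyGridError("no current-use spells")
    if np.any(dur < 0):
        raise ValueError("durations must be non-negative")
    maxd = float(max_duration) if max_duration is not None else dur.max()
    if maxd <= 0:
        raise EmptyGridError("all spells have zero duration")
    boundaries = np.linspace(0.0, maxd, n_periods + 1)
    width = boundaries[1] - boundaries[0]

    lower = boundaries[:-1]
    person_time = np.clip(dur[None, :] - lower[:, None], 0.0, width).sum(axis=1)

    ev_pos = np.clip(dur[obs], 0.0, maxd)
    idx = np.minimum((ev_pos / width).astype(int), n_periods - 1)
    events = np.bincount(idx, minlength=n_periods).astype(float)
    return DurationGrid(boundaries=boundaries, events=events,
                        person_time=person_time)


def smooth_hazard(grid: DurationGrid, kernel: str = "epanechnikov",
                  bandwidth_periods: float = 10.0) -> SmoothedHazard:
    """Ramlau-Hansen smoothing of the grid's Nelson-Aalen increments.

    ``bandwidth_periods`` is the kernel half-width in grid periods;
    reflection at 0 and at the maximum duration corrects the boundary
    bias.  Evaluated at the period midpoints.
    """
    if bandwidth_periods <= 0:
        raise ValueError("bandwidth must be positive")
    k = KERNELS[kernel]
    b = bandwidth_periods * grid.width
    t = grid.midpoints
    dh = grid.increments()
    src = grid.midpoints
    top = grid.boundaries[-1]
    # reflect increments about both boundaries
    src_all = np.concatenate([src, -src, 2 * top - src])
    dh_all = np.concatenate([dh, dh, dh])
    u = (t[:, None] - src_all[None, :]) / b
    values = (k(u) * dh_all[None, :]).sum(axis=1) / b
    values = np.maximum(values, 0.0)
    return SmoothedHazard(times=t, values=values, bandwidth=b, kernel=kernel)


def hazard_ratio_curve(numerator: SmoothedHazard, denominator: SmoothedHazard,
                       floor: float = 1e-8) -> pd.DataFrame:
    """Pointwise ratio of two smoothed hazards on a shared grid.

    Points where the denominator falls below ``floor`` are masked (the
    ratio column holds NaN there and ``masked`` is True); no infinities
    propagate.
    """
    if numerator.times.shape != denominator.times.shape or not np.allclose(
        numerator.times, denominator.times
    ):
        raise ValueError("hazard curves are on different evaluation grids")
    masked = denominator.values < floor
    ratio = np.full_like(numerator.values, np.nan)
    ratio[~masked] = numerator.values[~masked] / denominator.values[~masked]
    return pd.DataFrame({
        "time": numerator.times,
        "numerator": numerator.values,
        "denominator": denominator.values,
        "ratio": ratio,
        "masked": masked,
    })
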
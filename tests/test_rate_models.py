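"""Poisson rate models against closed forms and a derivative-free
likelihood-maximisation oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from tzdcohort.rate_models import (
    DomainError,
    aggregate,
    fit_rate_model,
    incidence_rate,
    run_stratified,
    select_exposure,
    split_at_day,
)
from tzdcohort.timeutils import PERSON_YEAR_DAYS, year_start_day


def cells_to_segments(cells):
    """Expand (exposure, covariates, events, person_years) cells into
    segment rows the fitting API accepts."""
    seg = cells.copy()
    seg["duration"] = seg.pop("person_years") * PERSON_YEAR_DAYS
    seg["patient_id"] = np.arange(len(seg))
    seg["start"] = 0
    seg["end"] = seg["duration"]
    return seg


class TestIncidenceRate:
    def test_published_mortality_row_arithmetic(self):
        """469 all-cause deaths at 1.9/100 py imply ~24,684 py; 223
        circulatory deaths over that denominator give 0.9/100 py."""
        py = 100 * 469 / 1.9
        assert round(incidence_rate(223, py), 1) == 0.9

    def test_zero_events(self):
        assert incidence_rate(0, 500.0) == 0.0

    def test_arithmetic_identity(self):
        assert incidence_rate(5, 250.0) == 2.0

    @pytest.mark.parametrize("py", [0.0, -10.0])
    def test_nonpositive_person_time_rejected(self, py):
        with pytest.raises(DomainError):
            incidence_rate(3, py)


class TestCrudeTwoGroupModel:
    def test_rate_ratio_exact(self):
        """Saturated two-group model: RR equals the analytic rate ratio
        (20/1000py vs 10/1000py -> 2.0) and the Wald CI its closed form."""
        cells = pd.DataFrame({
            "exposure": ["ref", "trt"],
            "events": [10, 20],
            "person_years": [1000.0, 1000.0],
        })
        fit = fit_rate_model(cells_to_segments(cells), reference="ref",
                             adjustment="none")
        rr = fit.rr("exposure[trt]")
        assert rr == pytest.approx(2.0, abs=1e-10)
        se = np.sqrt(1 / 20 + 1 / 10)
        lcl, ucl = fit.ci("exposure[trt]")
        assert lcl == pytest.approx(2.0 * np.exp(-1.959963984540054 * se), rel=1e-7)
        assert ucl == pytest.approx(2.0 * np.exp(+1.959963984540054 * se), rel=1e-7)

    def test_no_events_rejected(self):
        cells = pd.DataFrame({"exposure": ["a", "b"], "events": [0, 0],
                              "person_years": [10.0, 10.0]})
        with pytest.raises(DomainError):
            fit_rate_model(cells_to_segments(cells), adjustment="none")


class TestConfounderFitOracle:
    def test_matches_nelder_mead_likelihood_maximiser(self):
        """Four hand-chosen cells with one binary confounder: GLM
        coefficients match a derivative-free likelihood maximiser to 1e-6."""
        cells = pd.DataFrame({
            "exposure": ["ref", "ref", "trt", "trt"],
            "conf": ["lo", "hi", "lo", "hi"],
            "events": [12, 30, 9, 60],
            "person_years": [800.0, 500.0, 300.0, 450.0],
        })
        fit = fit_rate_model(cells_to_segments(cells), reference="ref",
                             adjustment=["conf"])

        y = cells["events"].to_numpy(float)
        off = np.log(cells["person_years"].to_numpy())
        x_trt = (cells["exposure"] == "trt").to_numpy(float)
        # same parameterisation as the model: 'hi' (sorted first) is the
        # reference level, so the dummy marks 'lo'
        x_lo = (cells["conf"] == "lo").to_numpy(float)

        def negll(beta):
            eta = beta[0] + beta[1] * x_trt + beta[2] * x_lo + off
            return np.sum(np.exp(eta)) - np.sum(y * eta)

        res = optimize.minimize(negll, np.zeros(3), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 10000, "maxfev": 10000})
        got = {t: c for t, c in zip(fit.terms["term"], fit.terms["coef"])}
        assert got["intercept"] == pytest.approx(res.x[0], abs=1e-6)
        assert got["exposure[trt]"] == pytest.approx(res.x[1], abs=1e-6)
        assert got["conf[lo]"] == pytest.approx(res.x[2], abs=1e-6)


def test_aggregation_invariance():
    """Fitting on fine segments and on cells aggregated over the model's
    covariate cross-classification gives identical estimates (Poisson
    sufficiency)."""
    rng = np.random.default_rng(5)
    n = 400
    seg = pd.DataFrame({
        "patient_id": np.arange(n),
        "exposure": rng.choice(["a", "b"], n),
        "sex": rng.choice(["F", "M"], n),
        "duration": rng.integers(30, 2000, n).astype(float),
    })
    seg["start"] = 0
    seg["end"] = seg["duration"]
    rate = 0.01 * np.exp(0.5 * (seg["exposure"] == "b")
                         + 0.3 * (seg["sex"] == "M"))
    seg["events"] = rng.poisson(rate * seg["duration"] / PERSON_YEAR_DAYS)

    fine = fit_rate_model(seg, reference="a", adjustment=["sex"])
    cells = aggregate(seg, ["exposure", "sex"])
    coarse = fit_rate_model(cells_to_segments(cells), reference="a",
                            adjustment=["sex"])
    for term in ("exposure[b]", "sex[M]"):
        assert fine.rr(term) == pytest.approx(coarse.rr(term), rel=1e-8)
        assert fine.ci(term) == pytest.approx(coarse.ci(term), rel=1e-8)


def test_separation_reported_with_infinite_ci_sentinel():
    """A level with events but no comparator information is flagged and
    reported with the infinite-CI sentinel rather than crashing."""
    cells = pd.DataFrame({
        "exposure": ["ref", "trt", "trt"],
        "conf": ["lo", "lo", "hi"],  # 'hi' has no events: its MLE is -inf
        "events": [10, 10, 0],
        "person_years": [500.0, 500.0, 300.0],
    })
    fit = fit_rate_model(cells_to_segments(cells), reference="ref",
                         adjustment=["conf"])
    sep = fit.terms[fit.terms["separated"]]
    assert not sep.empty
    assert (sep["lcl"] == 0.0).all() and np.isinf(sep["ucl"]).all()


class TestStratified:
    def _segments(self):
        rng = np.random.default_rng(8)
        n = 600
        start = rng.integers(year_start_day(2004), year_start_day(2010), n)
        seg = pd.DataFrame({
            "patient_id": np.arange(n),
            "exposure": rng.choice(["a", "b"], n),
            "age_years": rng.integers(45, 90, n),
            "sex": rng.choice(["F", "M"], n),
            "state_insulin": rng.choice(["never", "current"], n, p=[0.8, 0.2]),
            "start": start,
        })
        seg["end"] = seg["start"] + rng.integers(50, 700, n)
        seg["duration"] = seg["end"] - seg["start"]
        seg["calendar_year"] = 2000
        seg["age_band"] = "60-64"
        seg["events"] = rng.poisson(0.02 * seg["duration"] / 365.25)
        return seg

    def test_empty_stratum_not_estimable(self):
        seg = self._segments()
        seg["state_insulin"] = "never"
        fits = run_stratified(seg, "insulin", reference="a", adjustment="none")
        assert fits["yes"] == "not-estimable"
        assert fits["no"] != "not-estimable"

    def test_degenerate_stratification_equals_pooled(self):
        seg = self._segments()
        seg["state_insulin"] = "never"
        pooled = fit_rate_model(seg, reference="a", adjustment="none")
        strat = run_stratified(seg, "insulin", reference="a",
                               adjustment="none")["no"]
        assert strat.rr("exposure[b]") == pytest.approx(
            pooled.rr("exposure[b]"), rel=1e-12)

    def test_calendar_split_divides_straddling_segment(self):
        """A segment spanning 2006-10-01..2007-03-01 is divided at the
        2007-01-01 boundary before fitting."""
        from tzdcohort.timeutils import to_day

        cut = year_start_day(2007)
        seg = pd.DataFrame({
            "patient_id": [1], "start": [to_day("2006-10-01")],
            "end": [to_day("2007-03-01")], "events": [0],
        })
        seg["duration"] = seg["end"] - seg["start"]
        out = split_at_day(seg, cut)
        assert len(out) == 2
        assert out["end"].iloc[0] == cut and out["start"].iloc[1] == cut
        assert out["duration"].sum() == seg["duration"].iloc[0]

    def test_age65_strata_partition_person_time(self):
        seg = self._segments()
        fits = run_stratified(seg, "age65", reference="a", adjustment="none")
        py = sum(f.exposure_table["person_years"].sum()
                 for f in fits.values() if f != "not-estimable")
        assert py == pytest.approx(seg["duration"].sum() / PERSON_YEAR_DAYS)


def test_select_exposure_priority_and_reference_check():
    seg = pd.DataFrame({
        "state_a": ["current", "past", "never"],
        "state_b": ["current", "current", "never"],
        "duration": [10.0, 10.0, 10.0], "events": [0, 0, 0],
    })
    sel = select_exposure(seg, {"a": ("a", "current"), "b": ("b", "current")},
                          reference="b")
    assert list(sel["exposure"]) == ["a", "b"]
    with pytest.raises(ValueError):
        select_exposure(seg, {"a": ("a", "current")}, reference="zzz")
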
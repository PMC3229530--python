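# Methods

`tzdcohort` implements an active-comparator pharmacoepidemiologic
safety study as a testable pipeline: synthetic primary-care records
with known ground truth feed new-user cohort construction,
time-dependent exposure classification, Poisson rate models, smoothed
duration-of-use hazards and Kaplan-Meier life tables. This note
documents the models, the conventions, the knobs that matter, and what
the synthetic data can and cannot show.

## Time and calendar conventions

All dates are integer days since 1990-01-01 and all intervals are
half-open `[start, end)`. Fixed constants: "3 months" = 91 days,
"12 months" = 365 days (exposure windows), one month = 30.44 days where
fractional month arithmetic is needed, 1 person-year = 365.25 days,
life-table horizons 1 y = 365 d and 3 y = 1095 d. Birth dates are
anonymised to a year; ages use a mid-year (July 1) birthday. The
one-year eligibility run-in is boundary-inclusive: an index exactly
365 days after data start qualifies.

## The synthetic record generator

The generator emits the five record tables the analysis consumes, plus
a ground-truth sidecar holding every latent draw (severity, the unit
exponential variates behind each initiation, discontinuation and
outcome time), so any patient's hazard trajectory can be recomputed
exactly.

**Population.** Ages are truncated normal (mean 64, sd 12, floor 40);
56% male; patients cluster in practices, a configurable fraction of
which (default 40%) are linked to hospital data (available from
1997-04-01) and death certificates (from 2001-01-01). Observation
windows start uniformly over the calendar span (default 1998–2010)
with exponential durations (mean 8 y, minimum 1 y). A standard-normal
latent *severity* score per patient is the deliberate unmeasured
confounder: it raises initiation hazards of channelled classes
(insulin by default) and outcome hazards, and is visible to the
analysis only through noisy comorbidity-flag proxies
(P(flag) = logistic in severity).

**Prescribing.** First-ever initiation of each class follows a
piecewise-constant hazard over calendar years: a baseline rate times a
per-year multiplier (defaults reproduce the post-2007 collapse of
rosiglitazone initiation and the rise of pioglitazone) times
exp(channeling x severity). After initiation, repeat prescriptions
recur every ~60 days (uniform ±20% jitter) until an exponentially
distributed discontinuation. A fraction of thiazolidinedione
prescriptions are multi-constituent with metformin and enter both
class histories. The 60-day repeat cycle is a free choice (no source
states prescription duration) and is configurable.

**Outcomes.** Death, ACS, stroke and heart failure are competing
piecewise-constant hazards, inverted exactly per constant piece (no
discretisation error — this is what makes the calibration tests
sharp). The hazard pieces are the very person-time segments produced
by the exposure-history engine over the patient's full observation
window, so generator and analysis share one set of window rules by
construction. Each outcome's log-hazard is baseline + age (per decade)
+ male + 0.25 x comorbidity count + severity coefficient x severity
+ the true log RR of every currently used class (optionally a
duration-dependent early/late pair measured from the first
prescription, used by the early-excess scenario). Nonfatal events are
censored at death; hospital event records exist only for linked
practices inside the hospital window (70% capture); certificate deaths
draw a primary cause from a per-class multinomial over ICD-10
chapters, then a representative code within the chapter.

## Cohorts and matching

The overall exposed cohort indexes at the first insulin/OAD
prescription at least one year after data start at age >= 40 (type-1
patients excluded by flag). Inception cohorts require the *first-ever*
prescription of the class after the run-in; earlier use of other
classes does not exclude, so patients belong to multiple inception
cohorts — together with time-dependent classification this is the
guard against immortal time bias. Censoring is
min(end of collection, day after death), so the death day lies inside
the half-open follow-up. In between-drug comparisons each cohort is
additionally censored at the first prescription of the comparator.

Controls are matched 1:1 on sex and practice within 5 years of age at
the same index date, nearest age first, ties broken by a seeded draw;
a control serves one exposed patient and is censored at their own
first diabetes prescription. Candidates are required only to have no
diabetes prescription *before* the index: restricting the pool to the
never-treated instead would condition on the future (patients who die
early never get treated) and measurably inflates control mortality —
we verified this failure mode directly before settling on the rule.
Unmatched exposed patients are flagged, never dropped.

## Exposure person-time

Per class and day: *current* within 91 days of a prescription
(overlapping windows merge, so a repeat extends current use), *recent*
91–365 days after the most recent prescription, *past* beyond 365
days, *never* before the first. Follow-up is partitioned at every
state change of every class, calendar-year boundary, age-band
birthday and covariate change; segments tile `[index, censor)`
exactly (property-tested, and re-verified against a brute-force
day-by-day classifier). Covariate snapshots take the most recent value
before segment start; co-medication records expire after 183 days
(a 6-month prescribing lookback). Each patient's first event of an
outcome is counted in the unique segment containing it (boundary
events belong to the segment starting that day); with the
incident-only rule a patient with a pre-index record of a nonfatal
outcome contributes no person-time to that outcome (deaths are never
excluded this way); a death truncates its segment the day after.

## Rate models

Segments are aggregated to cells over the exposure term and the
adjustment covariates (by Poisson sufficiency this changes nothing —
asserted by a test) and fitted by Poisson GLM with log person-year
offset (statsmodels IRLS, 200 iterations, parameter tolerance 1e-10).
Age enters as 10-year bands (85+ top), calendar year as categorical.
Minimal adjustment: age band, sex, calendar year. Full adjustment
adds smoking/alcohol/BMI (absent values are their own category),
comorbidity-history flags, recent co-medication, socioeconomic
quintile (only in linked-practice analyses), and current-use
indicators of the other drug classes. CIs are Wald, exp(b ± 1.96 se).

Degenerate designs are handled explicitly: exactly collinear dummy
columns are pruned by a greedy left-to-right rank test (intercept and
exposure terms first, so they are never the ones dropped); under
(quasi-)separation the drifting levels are flagged and reported with a
[0, inf) CI sentinel while a flat-deviance fit (relative change
< 1e-5 at the iteration cap) is accepted — the non-separated
coefficients, including the exposure term, are stable there. A fit
whose deviance is still genuinely improving raises a convergence
error, which the study driver reports as not-estimable.

## Duration-of-use hazards

Current-use spells run from the inception prescription to the first
exit from current use (91 days after the last prescription of an
unbroken repeat run), censoring or the event. The spell axis is cut
into 100 equal-width periods; the per-period Nelson-Aalen increment is
d_i / Y_i with Y_i = person-time/width (the average number at risk);
the Ramlau-Hansen estimate is the kernel-weighted sum of increments,
Epanechnikov kernel, default bandwidth 10 periods, reflection at both
boundaries (preserving the cumulative-hazard mass to within the
tested 2% interior error). The comparison curve is the ratio of two
separately smoothed hazards — an interpretation, not a smoothed ratio
— on a shared grid, masked where the denominator vanishes or where
fewer than `min_at_risk` spells (default 20) remain: a kernel estimate
over a handful of residual spells is noise. Whether the 100 periods
should be equal-width in time or in events is not specified anywhere;
equal width in time is implemented.

## Life tables

Product-limit survival with events-before-censorings tie handling,
Greenwood variance, and cumulative incidence 100·(1−S) with log(−log)
95% CIs (which respect the [0, 100] range). Horizons of 1 and 3
years; a horizon beyond the data carries the last value forward with
an `extrapolated` flag. Excess risk is the difference of cumulative
incidences computed at full precision and rounded only for display.
Spells end at exit from current use (configurable in principle; the
intention-to-treat-like alternative is not implemented). Competing
risks are ignored by construction (Kaplan-Meier, not Aalen-Johansen) —
a known limitation shared with the design this emulates.

## Study driver and the bias gate

Set 1 compares past use of each class (insulin, sulphonylurea,
pooled thiazolidinedione, metformin) with matched controls and with
past metformin, minimally and fully adjusted. Past use is a
negative-control exposure: a fully adjusted past-use RR away from 1 is
flagged as a residual-confounding signal. The within-class current-use
comparison (set 2) is gated on the past rosiglitazone vs past
pioglitazone death RR covering 1 — the threshold is a configuration
choice, not an established cutoff — and a failed gate caveats the
report rather than suppressing it. Hospital and death-certificate
analyses restrict person-time to linked practices inside the
respective linkage windows. The cause-of-death table shares one
current-use person-time denominator across all chapter rows, so
event-weighted chapter rates rebuild the all-cause rate exactly
(asserted). Reports are deterministic files; the run manifest records
config, seed and every design flag in force.

## Validation experiments and problem sizes

`tzdcohort.validation` re-derives the pipeline's guarantees with
independent oracles; `scripts/acceptance.py` runs them end to end.
Problem sizes are chosen so the full battery completes in a few
minutes on one core while keeping each check well-powered: 200 random
patients for the day-loop exposure oracle; 300 spells for the KM
risk-set comparison; 600/6000-patient populations for the
conservation and cause-partition invariants; 50 replicates of 3000
patients for CI coverage of the known current-use death RR (1.2);
9000 patients for the channeling and null bias scenarios; 6000 for
the early-excess duration shape. Coverage of a 95% CI is
n-independent, which is what lets the coverage experiment run at
3000 patients per replicate.

One deliberate testing choice: in the channeling scenario the
*expected* attenuation of the past-insulin RR from adjusting for the
comorbidity proxies is ~0.13 on the log scale, below single-replicate
Monte-Carlo resolution at these sizes, so no test asserts
`adjusted < crude` on one seed. The tests instead assert the
well-powered decomposition — crude RR > 1, proxy-adjusted RR still
> 1, and adjustment for the *true* latent severity (possible only
because the sidecar stores it) collapsing the RR to compatibility
with 1.

## What the generator does and does not emulate

It reproduces the statistical structure the analyses rely on:
practice-clustered enrolment with partial linkage, calendar-trended
initiation, repeat-prescription exposure persistence,
confounding-by-severity with only proxy observability, drug effects on
outcome hazards with configurable truth, and source-restricted
recording. It does not attempt real-world marginals beyond those
qualitative patterns: no free-text or code-list clinical coding, no
dose or adherence, no stockpiling, no restarting of a class after
discontinuation, no treatment switching driven by disease
progression, no multiple imputation of covariates, and severity is a
single scalar. Passing tests therefore demonstrate that
the *methods* recover known truth under the stated data-generating
assumptions — not that any particular real-world estimate is correct.

## Known limitations

* Kaplan-Meier cumulative incidence overstates absolute risk in the
  presence of competing death for nonfatal endpoints.
* The Poisson models use model-based (not robust) variances and no
  practice-level random effects.
* Separation is reported, not resolved (no Firth-type penalisation).
* The duration-hazard curve has no confidence band; read it only where
  the at-risk mask leaves it unmasked.
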
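# tzdcohort

A pharmacoepidemiologic safety-study pipeline for comparing
cardiovascular outcomes and mortality between thiazolidinediones
(rosiglitazone vs pioglitazone) in primary-care records — built as a
fully synthetic, fully testable analysis. Real studies of this
question use proprietary UK primary-care data linked to hospital
episodes and death certificates; here a generator emits records with
the same statistical structure and *known* ground truth, so every
stage of the analysis can be validated against the truth that
produced the data.

It is aimed at pharmacoepidemiologists and biostatisticians who want
a worked, tested implementation of the new-user active-comparator
design: inception cohorts with matched controls, time-dependent
exposure person-time, negative-control bias analysis, Poisson rate
models, kernel-smoothed duration-of-use hazards, and Kaplan-Meier
life tables.

## The design in brief

Exposure to each drug class is classified in a time-dependent manner
from the prescription stream: **current** use within 3 months of a
prescription (repeat prescriptions extend the window), **recent** use
3–12 months after the most recent prescription, **past** use beyond
12 months. Follow-up is split into person-time segments homogeneous
in exposure and covariates; because treated time can begin only at the
first prescription, immortal time is excluded by construction.

Incidence rates are contrasted with log-linear Poisson models with a
person-time offset,

```
log E[d_i] = log(py_i) + beta_exposure + beta_age + beta_sex + beta_year + ...
RR = exp(beta_exposure),  95% CI = exp(beta +/- 1.96 se)
```

Four analysis sets mirror the study design:

1. **Bias analysis** — outcome rates during *past* use of each class
   vs matched diabetes-free controls and vs past metformin. Past use
   is a negative-control exposure: adjusted RRs that stay away from 1
   measure residual confounding by the underlying disease.
2. **Current-use comparison** — adjusted RRs for death, ACS, stroke
   and heart failure during current rosiglitazone vs current
   pioglitazone use, per data source, stratified by age, insulin
   co-prescribing and calendar time; gated on (1).
3. **Duration of use** — current-use follow-up divided into 100
   periods; Nelson-Aalen hazard increments smoothed with an
   Epanechnikov kernel (the Ramlau-Hansen estimator,
   `h(t) = b^-1 sum_i K((t-t_i)/b) dH_i`); the rosiglitazone :
   pioglitazone ratio curve shows how risk evolves after starting.
4. **Life tables** — Kaplan-Meier cumulative incidence at 1 and 3
   years of current use with Greenwood/log(-log) CIs and excess-risk
   differences, overall and by age band and sex.

Plus a cause-of-death table: ICD-10-chapter-specific mortality over a
shared current-use person-time denominator.

The synthetic generator (`tzdcohort.synthetic_ehr`) encodes the
threats these methods exist to handle: a latent severity score
channels sicker patients to insulin and raises outcome hazards while
being observable only through noisy comorbidity proxies
(confounding by severity); drug initiation follows calendar trends
(rosiglitazone initiation collapses after 2007); hospital and
death-certificate records exist only for linked practices within
their collection windows.

## Worked example

```
python analysis/01_simulate_cohort_data.py
python analysis/02_build_cohorts.py
python analysis/03_bias_analysis.py
python analysis/04_current_use_comparison.py
python analysis/05_duration_of_use.py
python analysis/06_life_tables.py
```

Step 01 simulates 12,000 patients (seed 20111202) and prints the
calendar pattern the generator encodes — rosiglitazone initiations
collapsing after 2007 (217 in 2006, 119 in 2007, 20 in 2008) while
pioglitazone rises (69 → 126 → 201). Step 02 builds the cohorts:

```
overall exposed cohort: 6,111 patients
  inception rosiglitazone :    692
  inception pioglitazone  :    625
matched controls: 4,801 (1,304 exposed unmatched, flagged not dropped)
```

Step 03 runs the negative-control analysis and prints the gate for
the within-class comparison:

```
bias gate (past rosiglitazone vs past pioglitazone, death):
  RR 0.874 [0.514, 1.486] -> within-class comparison permitted
```

i.e. past users of the two drugs die at statistically
indistinguishable rates, so the populations are comparable enough for
a head-to-head contrast. Step 04 then prints, among others:

```
death          (gp      ) RR 1.86 [1.16, 2.99] (71 events, 6.08/100py)
heart_failure  (gp      ) RR 2.73 [1.12, 6.68] (30 events, 2.61/100py)
stroke         (hospital) not estimable
```

The generator's ground truth sets the current-use death RR to 1.2 and
heart failure to 1.7; with only ~650 users per arm the estimates are
noisy but their CIs cover the truth, and contrasts whose fit is
degenerate (too few linked-hospital events) are reported
not-estimable rather than as spurious numbers. Step 05 reports the
smoothed mortality-RR curve over duration of current use (masked
where fewer than 50 patients remain at risk), and step 06 the excess
risks, e.g. `all +3.44` additional deaths per 100 patients over 3
years of rosiglitazone vs pioglitazone in this replicate.

All tables land under `results/`.

## Layout

```
src/tzdcohort/        library: config, synthetic_ehr, cohort_builder,
                      exposure_history, rate_models, duration_hazard,
                      life_tables, icd10, orchestrator, scenarios,
                      validation, io, cli
analysis/             numbered narrative drivers (01..06)
tests/                pytest suite incl. acceptance tests
scripts/acceptance.py end-to-end validation run
docs/methods.md       models, conventions, design choices, limitations
```

A `tzdstudy` console script exposes the stages
(`simulate`, `build-cohorts`, `split-exposure`, `run-study`) for shell
use; `tzdstudy run-study --out <dir> --seed <n>` runs everything and
renders the report tables.
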
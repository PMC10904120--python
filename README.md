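# cvdsim

An individual-level cardiovascular disease (CVD) microsimulation policy
model for projecting lifetime health outcomes — disease events, survival
and quality-adjusted life years (QALYs) — and the impact of statin
treatment policy across socioeconomic deprivation strata.

It is written for health economists and epidemiological modellers who
need more than a fixed-horizon risk score: a policy model that tracks
each person's evolving disease history, accounts for competing risks,
and turns risk-factor profiles into lifetime projections that can be
standardized, compared across subgroups, and stressed under treatment
scenarios.

## The model

Seven endpoints are simulated: first myocardial infarction (MI), stroke,
coronary revascularisation (CRV), incident cancer, incident diabetes,
vascular death and nonvascular death. Each endpoint's risk follows a
Gompertz proportional-hazards equation on the age timescale:

    log h_e(age, x) = β₀ + β₁ · (age − 60) + x'β

where `x` contains entry characteristics (sex, ethnicity, smoking, BMI
category, lipids, blood pressure, HbA1c, creatinine, treated
hypertension, physical activity, diet quality, severe mental illness,
Townsend deprivation quintile) and time-updated event-history terms with
separate year-of-event and subsequent-years effects (e.g. a same-year MI
raises vascular-death risk far more than an old one). Separate equations
apply to people without and with CVD history; cancer and diabetes
equations are pooled.

Simulation proceeds in annual cycles: each year the applicable endpoints
are evaluated in a uniformly random order with firing probability
`1 − exp(−h)`; events fired earlier in a cycle feed the hazards of later
draws; death ends the trajectory; survivors age one year, to a cap of
110. An integrated linear EQ-5D utility model (range −0.594 to 1)
converts each simulated year into QALYs, with year-of-event and
subsequent-years decrements for MI and stroke, duration-split decrements
for diabetes, and a cancer-history decrement.

Around the simulator the package provides:

- **Estimation** — maximum-likelihood Gompertz PH fits on annually split
  person-year episodes, person-level bootstrap ensembles for
  probabilistic sensitivity analysis (PSA);
- **Calibration / validation** — baseline recalibration against observed
  cumulative incidence (Aalen–Johansen, competing-risk aware) and
  predicted-vs-observed validation reports;
- **Treatment policy** — guideline-style statin eligibility (10-year
  risk ≥ 10%, type 1 diabetes, eGFR < 60, albuminuria; high-intensity
  dosing for secondary prevention), LDL-mediated hazard reductions, and
  full-coverage vs real-world-uptake scenario contrasts under common
  random numbers;
- **Population analysis** — direct standardization to a sex × age band ×
  deprivation quintile reference population and quintile-gap summaries;
- **Synthetic data** — generators for cohorts, follow-up data from known
  equations (an independent continuous-time sampler used as the engine's
  oracle), utility surveys and reference weights, so everything runs
  without access-controlled data.

## Worked example

Project outcomes for a 60-year-old white man: never-smoker, overweight
(BMI 25–30), deprivation quintile 3, moderately active, healthy diet,
LDL 3.6 / HDL 1.0 mmol/L, creatinine 82 µmol/L, BP 140/80, HbA1c 40,
no treatment and no disease history, using the packaged synthetic
equations:

```python
from cvdsim import CVDMicrosimulation, ten_year_mve_risk
from cvdsim.synthetic import fixture_coefficient_set, typical_profile

coefficients = fixture_coefficient_set()
person = typical_profile()

ten_year_mve_risk(person, coefficients, reps=500, seed=1)
# 9.8   (% risk of a first major vascular event within 10 years)

model = CVDMicrosimulation([person], coefficients)
print(model.simulate(replicates_per_person=500, master_seed=1).summary())
```

```
CVD microsimulation summary
===========================
persons: 1   replicates/person: 500
mean remaining life years: 22.32
mean QALYs:                18.89
deaths: vascular 23.2%, nonvascular 76.8%, censored alive 0.0%
lifetime cumulative incidence:
  mi                 0.176
  stroke             0.156
  crv                0.108
  cancer             0.294
  diabetes           0.346
  vascular_death     0.232
  nonvascular_death  0.768
```

Reading: across 500 simulated lifetimes this man lives 22.3 more years
on average (18.9 QALYs once annual utility is applied), has a 9.8%
10-year and 17.6% lifetime first-MI risk, and dies of a vascular cause
in 23% of lifetimes. All numbers derive from the synthetic coefficient
fixture, not from fitted trial or cohort data.

A `cvdsim` command-line tool exposes the same pipeline
(`synth`, `fit`, `calibrate`, `validate`, `simulate`, `scenario`, `psa`)
driven by a YAML config; see `docs/example_config.yaml`.

## Layout

```
src/cvdsim/
  registry.py      shared covariate registry (names, coding, centring)
  profiles.py      IndividualProfile / DynamicState, cohort CSV IO
  coefficients.py  risk equations, QoL model, coefficient JSON IO
  risk.py          linear predictors, annual hazards, 10-year MVE risk
  engine.py        the annual-cycle microsimulation (scalar + vectorized)
  qol.py           EQ-5D utility prediction and OLS fitting
  estimation.py    Gompertz PH fitting, bootstrap, calibration, validation
  treatment.py     statin rules, treatment effects, scenario contrasts
  population.py    category summaries, standardization, quintile gaps
  synthetic.py     cohort/follow-up/survey/reference generators + fixture
  model.py         CVDMicrosimulation / GompertzPHRegression front end
  cli.py           command-line entry points
docs/methods.md    modelling assumptions, parameters, limitations
```
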
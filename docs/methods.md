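# Methods

## Model structure

The simulator is a discrete-time individual-level state-transition model
with an annual cycle. A person is a fixed baseline profile (entry
characteristics) plus a dynamic state: current age, alive/dead with
cause, first-occurrence flags for MI, stroke, coronary
revascularisation, cancer and diabetes (each in phase never →
year-of-event → prior-years), years since each event, diabetes duration,
and treatment status. Seven endpoints compete: the five first-occurrence
disease events plus vascular and nonvascular death. Simulation runs
until death or age 110; survivors at the cap are censored alive.

Within one cycle the applicable endpoints (those not already in history,
plus both deaths) are evaluated sequentially in a uniformly random
order. Each evaluated endpoint fires with probability `1 − exp(−h)`
where `h` is its current annual hazard. By default, events fired earlier
in the same cycle update the state before later endpoints are evaluated
(`within_cycle_updates=True`), so a same-year MI already raises
same-year vascular-death risk — this matches the year-of-event hazard
structure, where such effects are largest. A flag switches to
start-of-cycle hazards throughout if the alternative convention is
wanted. Death ends the cycle immediately.

## Hazards

Each endpoint/population pair has a Gompertz proportional-hazards
equation on the age timescale:

    log h = (β₀ + s₀) + (β₁ + s₁)(age − age_centre) + x'β + log m

- β₀: log hazard per year at the centring age (default 60) for the
  reference covariate pattern;
- β₁: per-year-of-age log-hazard slope (Gompertz);
- s₀, s₁: additive calibration shifts, default 0;
- x'β: registry covariates — entry characteristics plus the dynamic
  event-history terms (`mi_this_year` / `mi_prior_years`, …, `crv_any`,
  `cancer_any`, diabetes duration bands split at 10 years, and an HbA1c
  term applied only while no diabetes is diagnosed);
- log m: per-person per-endpoint treatment multiplier (0 untreated).

People with any CVD history at entry are routed to the secondary-
prevention equations for their whole simulated lifetime; incident events
in primary-prevention people act through the event-history covariates of
the primary-prevention equations. Cancer and diabetes equations are
pooled across the two populations. The Gompertz family was chosen
because a log hazard linear in attained age makes the annual
time-update exact (the within-year hazard is constant, so the annual
cycle discretizes a well-defined continuous-time model); the baseline
could be swapped without touching the cycle logic.

The constant-within-cycle discretization `p = 1 − exp(−h)` has error
≤ h²/2 relative to the continuous-time one-year marginal; the property
suite checks engine-vs-continuous-time agreement directly.

## Quality of life

Annual utility is a linear function of characteristics and disease
history, clamped to the EQ-5D-3L range [−0.594, 1]. Year-of-event
decrements apply for exactly one annual cycle, then the subsequent-years
decrement (mirroring the hazard phase structure); diabetes decrements
split at 10 years from diagnosis; cancer carries a single any-history
decrement. QALYs accumulate utility × exposure per cycle. The utility
model is fitted by OLS on survey-style records (utilities already on the
3L value scale; no descriptive-system mapping is performed here).

## Accounting conventions

- Half-cycle correction on by default: the death year contributes 0.5
  life years and 0.5 × utility; full years otherwise. This is the
  standard discrete-time correction for events occurring on average
  mid-cycle.
- Discounting defaults to 0; when set, both life years and QALYs are
  discounted at `(1+r)^−(cycle+0.5)`.
- Per-horizon outputs (10-year, 20-year cumulative incidence, life
  years, QALYs) are accumulated during the same lifetime run.

## Randomness and common random numbers

Per replicate, a single PCG64 stream (seeded
`SeedSequence(master_seed, spawn_key=(0, replicate))`) yields two
uniform matrices per cycle: one per (person, endpoint) for the ordering
(order = argsort, a uniformly random permutation with fixed stream
consumption) and one for the event triggers, indexed by endpoint
identity rather than draw position. Draws are therefore a pure function
of (seed, replicate, cycle, person, endpoint): runs are bitwise
reproducible, and treatment scenarios that only modify hazards reuse
identical uniforms — common random numbers — so treated-vs-control
contrasts are exact per-person differences. Treatment-uptake draws use a
separate substream (`spawn_key=(1, replicate)`) so they never perturb
event randomness.

Two implementations share this draw discipline: a scalar reference path
(`simulate_cycle`/`simulate_individual`, readable, with an audit utility
stream) and a vectorized cohort path; for a single person they produce
identical trajectories, which is itself under test.

## Estimation

Risk equations are fitted by maximum likelihood on annually split
person-year episodes: each person contributes one row per year at risk
for the endpoint (exposure = fraction of the year, event indicator,
mid-episode age, covariates reconstructed from the observed event
history). With piecewise-constant annual hazards the likelihood is
Poisson with a log-exposure offset; it is maximised by a small
Newton–Raphson/IRLS routine (standard errors from the inverse Fisher
information), cross-checked in the tests against statsmodels' Poisson
GLM on the same design. Constant covariates are dropped and reported,
never silently zeroed.

Bootstrap ensembles resample persons with replacement, implemented as
frequency-weighted refits on the precomputed episode tables (a person
drawn k times contributes weight k) — the identical estimator without
rebuilding episodes per replicate. One cohort resample per replicate
drives all refitted equations jointly. Replicate 0 is the point
estimate; PSA intervals are empirical 2.5/97.5 percentiles over
replicates ≥ 1.

## Observed incidence, calibration, validation

Observed cumulative incidence uses the Aalen–Johansen estimator with
death from other causes as a competing risk (the same estimand the
simulator produces); a 1 − Kaplan–Meier variant is available. Curves
are read as step functions, never linearly interpolated.

Calibration estimates an additive intercept shift (optionally also a
slope shift) on each equation's log baseline by minimising the sum over
follow-up years of squared differences between predicted and observed
cumulative incidence. The predicted curve is deterministic: model
hazards are evaluated on the target data's *observed* risk sets and
event histories, averaged per year with exposure weights, and combined
with the observed at-risk fraction — so predicted and observed curves
share risk sets exactly and the search objective carries no Monte Carlo
noise. Doubling every true hazard is recovered as a shift of log 2 (a
property under test). The shift-0 objective is always evaluated, so
calibration can never worsen the fit; reports carry pre/post
discrepancies.

Validation simulates the target cohort with the candidate equations and
tabulates predicted vs observed cumulative incidence per endpoint, year
and subgroup, with per-endpoint horizons (e.g. shorter incident-diabetes
follow-up) and ratio/difference summaries; empty subgroups are reported
as skipped. Note the ratio's Monte Carlo noise is ≈ 1/√(observed
events): tests judge cells against event-count-aware tolerances.

## Treatment policy

Eligibility is a pure function of the profile: any CVD history →
high-intensity statin (step-down when eGFR < 60 mL/min/1.73 m²);
otherwise treatment at 10-year CVD risk ≥ 10%, type 1 diabetes,
eGFR < 60, or albuminuria. eGFR, when not supplied, is derived from
creatinine, age and sex by the CKD-EPI 2021 race-free equation (recorded
as such in output metadata). The 10-year risk input is an external score
carried on the profile; the synthetic cohort generator fills it with a
deterministic synthetic risk index, and the model-internal
`ten_year_mve_risk` is available as an alternative source.

Treatment effects are deliberately configuration, not defaults: a
regimen removes a configured fraction of baseline LDL, and each affected
vascular endpoint's hazard is multiplied by
`rate_ratio_per_mmol ** ΔLDL`. The risk equations keep entry LDL as a
static covariate (they are adjusted for characteristics at entry), so
treatment acts only through the multipliers — no double counting.
Scenarios assign treatment once at entry, with per-quintile uptake
probabilities (full coverage = 1 everywhere), lifelong persistence, and
common-random-number counterfactuals.

## Synthetic data

The cohort generator draws from truncated-normal marginals for the
continuous biomarkers (joined by an optional exchangeable Gaussian
copula) and categorical shares for the rest, with defaults emulating a
large middle-aged UK cohort without CVD at entry: 44% male, age 56
(SD 8.1) within the 40–70 recruitment window, LDL 3.6 (SD 0.82) mmol/L,
deprivation quintile shares 37/20/16/14/12%, 4.9% prevalent diabetes,
7.4% prior cancer, and so on. It does not attempt to reproduce the full
joint covariate structure of any real cohort beyond these marginals and
the optional copula, nor cohort-specific selection effects (real
volunteer cohorts are healthier than the population) — so passing tests
demonstrate correctness of the machinery and qualitative patterns, not
quantitative agreement with any published cohort.

Follow-up data are sampled by an independent continuous-time
competing-risks routine: within each year, cause-specific exponential
times at the current hazards compete; the first under a year fires, the
history updates at the event time, remaining causes are redrawn for the
rest of the year. It shares the hazard definitions (the model itself)
with the engine but none of the event-drawing code, making the
engine-vs-sampler equivalence test a real cross-validation of the
discretization and ordering mechanics.

The packaged fixture coefficient file (`data/
synthetic_fixture_coefficients.json`, entirely synthetic) uses modest
Gompertz baselines (death-endpoint age slopes ≈ 0.095–0.105/year),
event-history effects largest in the year of the event, a protective
revascularisation effect on vascular death, a deprivation log hazard
ratio of log(1.15) per quintile step on stroke, diabetes and both
deaths, and published-scale EQ-5D decrements (MI −0.10/−0.07,
stroke −0.09/−0.13, diabetes −0.04/−0.08, cancer −0.03). Baseline rates
were set once to give realistic mid-life event rates (e.g. ≈10% 10-year
major-vascular-event risk for a moderate-risk 60-year-old man).

## Numerical choices and problem sizes

- Hazards are clipped in the IRLS at |log h| ≤ 30; non-finite simulated
  hazards raise a coefficient-file error rather than propagating NaNs.
- Calibration search: bounded Brent on [−4, 4] (Nelder–Mead for the
  two-parameter variant), tolerance 10⁻⁶, 200-iteration budget.
- Utility clamping is applied after the full linear prediction
  (idempotent).
- Ties in the random event order have probability zero (continuous
  uniforms); fixed orders are available for diagnostics.
- Default test/acceptance problem sizes (chosen to keep the suite
  minutes-scale while leaving comfortable statistical margins): 200,000
  draws for discretization checks; 20,000 persons × 5 replicates for
  engine-vs-sampler equivalence; n = 5,000 for ML recovery; 100
  repetitions × B = 200 at n = 1,000 for bootstrap coverage; 30,000
  persons for calibration recovery; 4,000 persons × 20–25 replicates
  for scenario contrasts. Production-style cohort projections would
  typically use 500 replicates per person, the package default.

## Known limitations

- No recurrent events: each disease endpoint occurs at most once, so
  second MIs/strokes act only through the prior-years hazard terms.
- Risk-equation population routing is fixed at entry; a primary-
  prevention person who suffers an MI stays on the primary-prevention
  equations (with MI-history terms) rather than switching equation sets.
- Annual cycles cannot order multiple events within a year beyond the
  random evaluation order; event times finer than a year are only
  available from the continuous-time sampler.
- Calibration adjusts baselines only (intercept, optionally slope),
  never covariate effects.
- Treatment effects are user-supplied configuration; no adherence decay
  or discontinuation is modelled.
- The oldest ages rely on extrapolating the Gompertz baselines well
  beyond the 40–70 entry window.
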
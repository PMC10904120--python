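"""Synthetic data generators.

Everything needed to exercise the model without restricted data: cohorts
whose marginal covariate distributions emulate a large UK middle-aged
population cohort without CVD at entry, individual follow-up data sampled
from known true risk equations by an independent continuous-time
competing-risks sampler (the engine's oracle), survey-style EQ-5D utility
records, and reference-population standardization weights.

The follow-up sampler shares no event-simulation code with the annual
engine: within each year it draws cause-specific exponential event times
from the current hazards, lets the first one under a year fire, updates
the history mid-year exactly per the model's rules and redraws the
remaining causes for the rest of the year. Comparing its output with the
engine validates the engine's annual discretization and random ordering.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import registry, risk
from .coefficients import CoefficientSet, read_coefficients
from .errors import ConfigError
from .estimation import FollowUpRecords
from .profiles import DynamicState, IndividualProfile, initial_state
from .registry import ENDPOINTS


@dataclass
class ContinuousMarginal:
    mean: float
    sd: float
    lo: float
    hi: float

    def ppf(self, u):
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return stats.truncnorm.ppf(u, a, b, loc=self.mean, scale=self.sd)


@dataclass
class CohortConfig:
    """Marginal distributions for the synthetic cohort.

    Defaults approximate a middle-aged UK cohort without prior CVD:
    44% male, age 56 (SD 8.1) truncated to the 40-70 recruitment window,
    LDL 3.6 (SD 0.82) mmol/L, deprivation quintile shares
    37/20/16/14/12%, and correspondingly for the other covariates.
    """

    male_fraction: float = 0.44
    age: ContinuousMarginal = field(default_factory=lambda: ContinuousMarginal(56.0, 8.1, 40.0, 70.0))
    ldl: ContinuousMarginal = field(default_factory=lambda: ContinuousMarginal(3.6, 0.82, 1.0, 8.0))
    hdl: ContinuousMarginal = field(default_factory=lambda: ContinuousMarginal(1.5, 0.37, 0.5, 3.5))
    hba1c: ContinuousMarginal = field(default_factory=lambda: ContinuousMarginal(35.8, 6.2, 20.0, 120.0))
    creatinine: ContinuousMarginal = field(default_factory=lambda: ContinuousMarginal(71.0, 15.0, 30.0, 200.0))
    sbp: ContinuousMarginal = field(default_factory=lambda: ContinuousMarginal(138.0, 19.0, 80.0, 220.0))
    dbp: ContinuousMarginal = field(default_factory=lambda: ContinuousMarginal(82.0, 10.0, 40.0, 130.0))
    ethnicity_shares: tuple = (0.95, 0.016, 0.016, 0.018)   # white/black/SA/other
    smoking_shares: tuple = (0.565, 0.332, 0.103)           # never/ex/current
    bmi_shares: tuple = (0.005, 0.337, 0.428, 0.169, 0.047, 0.014)
    physical_activity_shares: tuple = (0.329, 0.331, 0.15, 0.19)
    townsend_shares: tuple = (0.374, 0.202, 0.164, 0.143, 0.117)
    treated_hypertension: float = 0.16
    diabetes_fraction: float = 0.049
    type1_fraction_of_diabetes: float = 0.127   # 0.62% of 4.9%
    diabetes_duration_mean: float = 5.0
    cancer_fraction: float = 0.074
    mental_illness_fraction: float = 0.08
    unhealthy_diet_fraction: float = 0.36
    cvd_history_fraction: float = 0.0           # >0 adds a secondary-prevention mix
    statin_fraction: float = 0.0
    albuminuria_fraction: float = 0.03
    copula_rho: float = 0.0   # exchangeable Gaussian-copula correlation across
    #                           the continuous biomarkers (0 = independent)

    def __post_init__(self):
        for name in ("ethnicity_shares", "smoking_shares", "bmi_shares",
                     "physical_activity_shares", "townsend_shares"):
            shares = np.asarray(getattr(self, name), dtype=float)
            if (shares < 0).any() or shares.sum() <= 0:
                raise ConfigError(f"{name} must be nonnegative with positive sum")
            setattr(self, name, tuple(shares / shares.sum()))
        if not -0.99 < self.copula_rho < 0.99:
            raise ConfigError("copula_rho must be in (-0.99, 0.99)")


_CVD_HISTORY_MIX = [
    (frozenset({"MI"}), 0.50),
    (frozenset({"other_CHD"}), 0.19),
    (frozenset({"stroke"}), 0.078),
    (frozenset({"PAD"}), 0.064),
    (frozenset({"MI", "other_CHD"}), 0.168),
]

_CONTINUOUS_FIELDS = ("age", "ldl", "hdl", "hba1c", "creatinine", "sbp", "dbp")


def synthetic_ten_year_score(age, male, smoking, ldl, hdl, sbp,
                             treated_htn, diabetic, quintile) -> float:
    """Deterministic stand-in for an external 10-year CVD risk score (%).

    A fixed log-linear index of the major risk factors, scaled to produce
    plausible mid-life risks; synthetic, not a published score.
    """
    lp = (0.085 * (age - 50.0) + 0.40 * male
          + (0.55 if smoking == "current" else 0.12 if smoking == "ex" else 0.0)
          + 0.28 * (ldl - 3.6) - 0.50 * (hdl - 1.5) + 0.009 * (sbp - 138.0)
          + 0.30 * treated_htn + 0.65 * diabetic + 0.09 * (quintile - 1))
    h = 0.0035 * math.exp(lp)
    return 100.0 * -math.expm1(-10.0 * h)


def generate_cohort(n: int, seed: int, config: CohortConfig = None) -> list:
    """Draw n IndividualProfiles from the configured marginals.

    Continuous biomarkers use truncated-normal marginals joined by an
    exchangeable Gaussian copula (independent by default); categorical
    covariates are drawn independently. Deterministic per seed.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    k = len(_CONTINUOUS_FIELDS)
    rho = cfg.copula_rho
    if rho != 0.0:
        cov = np.full((k, k), rho)
        np.fill_diagonal(cov, 1.0)
        z = rng.multivariate_normal(np.zeros(k), cov, size=n,
                                    method="cholesky")
    else:
        z = rng.standard_normal((n, k))
    u = stats.norm.cdf(z)
    cont = {name: getattr(cfg, name).ppf(u[:, j])
            for j, name in enumerate(_CONTINUOUS_FIELDS)}
    sex = np.where(rng.random(n) < cfg.male_fraction, "male", "female")
    ethnicity = rng.choice(registry.ETHNICITIES, size=n, p=cfg.ethnicity_shares)
    smoking = rng.choice(registry.SMOKING_LEVELS, size=n, p=cfg.smoking_shares)
    bmi = rng.choice(registry.BMI_CATEGORIES, size=n, p=cfg.bmi_shares)
    pa = rng.choice(registry.PHYSICAL_ACTIVITY_LEVELS, size=n,
                    p=cfg.physical_activity_shares)
    quintile = rng.choice([1, 2, 3, 4, 5], size=n, p=cfg.townsend_shares)
    treated = rng.random(n) < cfg.treated_hypertension
    diabetic = rng.random(n) < cfg.diabetes_fraction
    type1 = rng.random(n) < cfg.type1_fraction_of_diabetes
    diab_dur = np.clip(rng.exponential(cfg.diabetes_duration_mean, n), 0.0, 30.0)
    cancer = rng.random(n) < cfg.cancer_fraction
    smi = rng.random(n) < cfg.mental_illness_fraction
    diet = rng.random(n) < cfg.unhealthy_diet_fraction
    has_cvd = rng.random(n) < cfg.cvd_history_fraction
    mix_labels = [m[0] for m in _CVD_HISTORY_MIX]
    mix_p = np.array([m[1] for m in _CVD_HISTORY_MIX])
    mix_p = mix_p / mix_p.sum()
    cvd_pick = rng.choice(len(mix_labels), size=n, p=mix_p)
    statin = rng.random(n) < cfg.statin_fraction
    albumin = rng.random(n) < cfg.albuminuria_fraction
    profiles = []
    for i in range(n):
        has_diab = bool(diabetic[i])
        diab_type = "none" if not has_diab else ("type1" if type1[i] else "type2")
        smoking_i = str(smoking[i])
        risk_pct = synthetic_ten_year_score(
            cont["age"][i], 1.0 if sex[i] == "male" else 0.0, smoking_i,
            cont["ldl"][i], cont["hdl"][i], cont["sbp"][i],
            1.0 if treated[i] else 0.0, 1.0 if has_diab else 0.0,
            int(quintile[i]))
        profiles.append(IndividualProfile(
            person_id=f"S{i:06d}",
            age_entry=float(cont["age"][i]),
            sex=str(sex[i]),
            ethnicity=str(ethnicity[i]),
            smoking=smoking_i,
            bmi_category=str(bmi[i]),
            ldl=float(cont["ldl"][i]),
            hdl=float(cont["hdl"][i]),
            hba1c=float(cont["hba1c"][i]),
            creatinine=float(cont["creatinine"][i]),
            sbp=float(cont["sbp"][i]),
            dbp=float(cont["dbp"][i]),
            treated_hypertension=bool(treated[i]),
            diabetes_history=diab_type,
            years_since_diagnosis=float(diab_dur[i]) if has_diab else 0.0,
            cancer_history=bool(cancer[i]),
            cvd_history=mix_labels[cvd_pick[i]] if has_cvd[i] else frozenset(),
            severe_mental_illness=bool(smi[i]),
            physical_activity=str(pa[i]),
            diet_unhealthy=bool(diet[i]),
            townsend_quintile=int(quintile[i]),
            statin_at_entry=bool(statin[i]),
            albuminuria=bool(albumin[i]),
            ten_year_cvd_risk=float(risk_pct),
        ))
    return profiles


# ---------------------------------------------------------------------------
# continuous-time follow-up oracle


class _OracleHazards:
    """Per-person cached hazard evaluation for the continuous-time sampler."""

    def __init__(self, profile: IndividualProfile, cs: CoefficientSet):
        self.profile = profile
        self.c = cs.centring
        self.parts = []
        for endpoint in ENDPOINTS:
            eq = cs.equation(endpoint, profile.population)
            static = (eq.baseline.log_hazard_intercept
                      + eq.calibration.intercept_shift
                      + risk.static_linear_predictor(profile, eq, self.c))
            slope = eq.baseline.age_slope + eq.calibration.slope_shift
            dyn_terms = []
            hb = 0.0
            for name, beta in eq.coefficients.items():
                canonical = registry.QOL_ALIASES.get(name, name)
                if canonical in registry.DYNAMIC_INDEX:
                    dyn_terms.append((canonical, beta))
                elif name == "hba1c_nondiabetic":
                    hb = beta
            self.parts.append((static, slope, dyn_terms, hb))
        self.hba1c_c = profile.hba1c - self.c["hba1c"]

    def hazards(self, state: DynamicState) -> list:
        ind = registry.dynamic_indicator_values(state)
        nondiab = state.event_flags["diabetes"] == "never"
        age_dev = state.current_age - self.c["age"]
        out = []
        for j, (static, slope, dyn_terms, hb) in enumerate(self.parts):
            lp = static + slope * age_dev
            for name, beta in dyn_terms:
                lp += beta * ind[name]
            if nondiab:
                lp += hb * self.hba1c_c
            out.append(math.exp(lp))
        return out


def generate_followup(cohort, true_equations: CoefficientSet,
                      max_years: float, seed: int) -> FollowUpRecords:
    """Sample follow-up IPD from known equations in continuous time.

    Within each year, cause-specific exponential times compete at the
    current hazards; the first under a year fires, histories update at
    the event time and the remaining causes are redrawn for the rest of
    the year. Ages and year-of-event phases update annually, matching the
    model's time structure but not its event-drawing mechanics.
    """
    rng = np.random.default_rng(seed)
    rows = []
    censor = {}
    for profile in cohort:
        hz = _OracleHazards(profile, true_equations)
        state = initial_state(profile)
        t_cens = min(float(max_years), registry.AGE_CAP - profile.age_entry)
        censor[profile.person_id] = t_cens
        year = 0
        dead = False
        while not dead and year < t_cens:
            t_in_year = 0.0
            year_len = min(1.0, t_cens - year)
            while True:
                h = hz.hazards(state)
                applicable = []
                for j, endpoint in enumerate(ENDPOINTS):
                    if endpoint in registry.EVENT_ENDPOINTS \
                            and state.event_flags[endpoint] != "never":
                        continue
                    applicable.append((j, endpoint, h[j]))
                best_t, best_e = math.inf, None
                for j, endpoint, hj in applicable:
                    if hj <= 0:
                        continue
                    t = rng.exponential(1.0 / hj)
                    if t < best_t:
                        best_t, best_e = t, endpoint
                if best_e is None or t_in_year + best_t >= year_len:
                    break
                t_in_year += best_t
                t_abs = year + t_in_year
                rows.append({"person_id": profile.person_id,
                             "endpoint": best_e, "time": t_abs})
                if best_e in ("vascular_death", "nonvascular_death"):
                    dead = True
                    break
                state.record_event(best_e)
            if dead:
                break
            state.roll_cycle()
            year += 1
    events = pd.DataFrame(rows, columns=["person_id", "endpoint", "time"])
    return FollowUpRecords(list(cohort), events, censor, float(max_years))


# ---------------------------------------------------------------------------
# utility survey


@dataclass
class SurveyMix:
    """Disease-history prevalence among synthetic survey respondents."""
    mi: tuple = (0.03, 0.09)          # (this_year, prior_years)
    stroke: tuple = (0.02, 0.08)
    diabetes: tuple = (0.06, 0.04)    # (duration < 10y, >= 10y)
    cancer: float = 0.10


def generate_utility_survey(n: int, true_qol, noise_sd: float, seed: int,
                            cohort_config: CohortConfig = None,
                            mix: SurveyMix = None,
                            centring: dict = None) -> pd.DataFrame:
    """Cross-sectional utility records: design columns + noisy utility.

    Covariates come from the cohort generator plus randomly assigned
    disease histories; utility = linear prediction + Gaussian noise,
    clamped to the EQ-5D-3L range. Columns are the covariate names of
    `true_qol` plus `utility`, ready for `fit_qol_model`.
    """
    from .qol import clamp_utility

    mix = mix or SurveyMix()
    c = dict(centring or registry.CENTRING_DEFAULTS)
    rng = np.random.default_rng(seed)
    cohort = generate_cohort(n, seed=int(rng.integers(2 ** 31)),
                             config=cohort_config)
    u_mi = rng.random(n)
    u_stroke = rng.random(n)
    u_diab = rng.random(n)
    u_cancer = rng.random(n)
    noise = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    records = []
    names = list(true_qol.coefficients)
    for i, p in enumerate(cohort):
        state = initial_state(p)
        # overwrite event history with the survey mix
        for ev in ("mi", "stroke", "diabetes", "cancer"):
            state.event_flags[ev] = "never"
        if u_mi[i] < mix.mi[0]:
            state.event_flags["mi"] = "this_year"
        elif u_mi[i] < mix.mi[0] + mix.mi[1]:
            state.event_flags["mi"] = "prior_years"
        if u_stroke[i] < mix.stroke[0]:
            state.event_flags["stroke"] = "this_year"
        elif u_stroke[i] < mix.stroke[0] + mix.stroke[1]:
            state.event_flags["stroke"] = "prior_years"
        if u_diab[i] < mix.diabetes[0]:
            state.event_flags["diabetes"] = "prior_years"
            state.diabetes_duration = 5.0
        elif u_diab[i] < mix.diabetes[0] + mix.diabetes[1]:
            state.event_flags["diabetes"] = "prior_years"
            state.diabetes_duration = 15.0
        if u_cancer[i] < mix.cancer:
            state.event_flags["cancer"] = "prior_years"
        row = {name: registry.resolve_covariate(name, p, state, c)
               for name in names}
        pred = true_qol.intercept + sum(
            true_qol.coefficients[nm] * row[nm] for nm in names)
        row["utility"] = clamp_utility(pred + noise[i], true_qol.bounds)
        records.append(row)
    return pd.DataFrame(records, columns=names + ["utility"])


# ---------------------------------------------------------------------------
# reference population and fixtures


def generate_reference_population():
    """Plausible mid-2020 UK-style standardization weights for ages 40-69:
    sex x 5-year age band x deprivation quintile (quintiles equal by
    construction of a quintile index)."""
    from .coefficients import ReferencePopulation
    band_shares = {"40-44": 0.160, "45-49": 0.165, "50-54": 0.180,
                   "55-59": 0.180, "60-64": 0.163, "65-69": 0.152}
    sex_shares = {"male": 0.492, "female": 0.508}
    weights = {}
    for sex, ws in sex_shares.items():
        for band, wb in band_shares.items():
            for q in range(1, 6):
                weights[(sex, band, q)] = ws * wb * 0.2
    return ReferencePopulation(weights=weights)


def fixture_coefficient_set() -> CoefficientSet:
    """The synthetic 'true' equations shipped with the package.

    Modest Gompertz baselines (age slopes ~0.09-0.11/year on the death
    endpoints), event-history effects largest in the year of the event, a
    protective revascularisation effect on vascular death, a deprivation
    log hazard ratio of log(1.15) per quintile step on stroke, incident
    diabetes and both deaths, and the published-scale EQ-5D decrements.
    Entirely synthetic values chosen for qualitative realism.
    """
    ref = importlib.resources.files("cvdsim") / "data" \
        / "synthetic_fixture_coefficients.json"
    with importlib.resources.as_file(ref) as path:
        return read_coefficients(path)


def typical_profile() -> IndividualProfile:
    """The documentation's worked-example individual: a 60-year-old white
    male never-smoker, overweight, deprivation quintile 3, moderately
    active, healthy diet, LDL 3.6 / HDL 1.0 mmol/L, creatinine 82 umol/L,
    BP 140/80 mmHg, HbA1c 40 mmol/mol, untreated, no disease history."""
    return IndividualProfile(
        person_id="typical", age_entry=60.0, sex="male", ethnicity="white",
        smoking="never", bmi_category="25-30", ldl=3.6, hdl=1.0, hba1c=40.0,
        creatinine=82.0, sbp=140.0, dbp=80.0, treated_hypertension=False,
        diabetes_history="none", years_since_diagnosis=0.0,
        cancer_history=False, cvd_history=frozenset(),
        severe_mental_illness=False, physical_activity="moderate",
        diet_unhealthy=False, townsend_quintile=3, statin_at_entry=False,
        ten_year_cvd_risk=12.6)
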
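"""Shared covariate registry.

Every coefficient map in a risk equation or QoL model draws its keys from
this single versioned registry, so fitted coefficients and simulation
covariates can never silently disagree on names or coding.

Coding conventions
------------------
* Reference levels: female, white ethnicity, never-smoker, BMI 18.5-25,
  physical activity high, Townsend quintile 1, no treatments or disease
  histories.
* Continuous covariates are centred at the centring constants carried in
  the coefficient file (defaults below), so the baseline log hazard refers
  to a person at the reference category with centred continuous values.
* `townsend_step` is the per-quintile-step linear deprivation term
  (quintile - 1, so quintile 1 contributes 0).
* Event-history covariates are phase-split: `<event>_this_year` is 1 only
  in the cycle the event fires, `<event>_prior_years` afterwards.
  Diabetes uses duration bands split at 10 years since diagnosis;
  `hba1c_nondiabetic` applies the (centred) HbA1c value only while the
  person has no diagnosed diabetes.
"""

from __future__ import annotations

REGISTRY_VERSION = "1"

# Model endpoints, canonical order (indices used throughout the engine).
ENDPOINTS = (
    "mi",
    "stroke",
    "crv",
    "cancer",
    "diabetes",
    "vascular_death",
    "nonvascular_death",
)
ENDPOINT_INDEX = {name: i for i, name in enumerate(ENDPOINTS)}
EVENT_ENDPOINTS = ENDPOINTS[:5]          # non-fatal, first occurrences only
DEATH_ENDPOINTS = ENDPOINTS[5:]
VASCULAR_ENDPOINTS = ("mi", "stroke", "crv", "vascular_death")
MVE_ENDPOINTS = VASCULAR_ENDPOINTS       # major vascular event components

POPULATIONS = ("no_cvd", "cvd", "pooled")
# diabetes and cancer equations are fitted across both populations
POOLED_ENDPOINTS = ("cancer", "diabetes")

SEXES = ("male", "female")
ETHNICITIES = ("white", "black", "south_asian", "other")
SMOKING_LEVELS = ("never", "ex", "current")
BMI_CATEGORIES = ("<18.5", "18.5-25", "25-30", "30-35", "35-40", "40+")
PHYSICAL_ACTIVITY_LEVELS = ("high", "moderate", "low", "missing")
DIABETES_TYPES = ("none", "type1", "type2")
CVD_HISTORY_EVENTS = ("MI", "stroke", "CRV", "PAD", "other_CHD")

CENTRING_DEFAULTS = {
    "age": 60.0,
    "ldl": 3.6,
    "hdl": 1.3,
    "hba1c": 36.0,
    "creatinine": 80.0,
    "sbp": 140.0,
    "dbp": 80.0,
}

EQ5D_FLOOR = -0.594   # worst EQ-5D-3L health state
EQ5D_CEILING = 1.0    # full health
AGE_CAP = 110         # simulate annually until death or this age


def _bmi_dummy(cat):
    def resolve(profile, centring):
        return 1.0 if profile.bmi_category == cat else 0.0
    return resolve


# name -> resolver(profile, centring) for covariates fixed at entry
STATIC_COVARIATES = {
    "male": lambda p, c: 1.0 if p.sex == "male" else 0.0,
    "ethnicity_black": lambda p, c: 1.0 if p.ethnicity == "black" else 0.0,
    "ethnicity_south_asian": lambda p, c: 1.0 if p.ethnicity == "south_asian" else 0.0,
    "ethnicity_other": lambda p, c: 1.0 if p.ethnicity == "other" else 0.0,
    "smoking_ex": lambda p, c: 1.0 if p.smoking == "ex" else 0.0,
    "smoking_current": lambda p, c: 1.0 if p.smoking == "current" else 0.0,
    "bmi_under_18_5": _bmi_dummy("<18.5"),
    "bmi_25_30": _bmi_dummy("25-30"),
    "bmi_30_35": _bmi_dummy("30-35"),
    "bmi_35_40": _bmi_dummy("35-40"),
    "bmi_40plus": _bmi_dummy("40+"),
    "ldl": lambda p, c: p.ldl - c["ldl"],
    "hdl": lambda p, c: p.hdl - c["hdl"],
    "creatinine": lambda p, c: p.creatinine - c["creatinine"],
    "sbp": lambda p, c: p.sbp - c["sbp"],
    "dbp": lambda p, c: p.dbp - c["dbp"],
    "treated_hypertension": lambda p, c: 1.0 if p.treated_hypertension else 0.0,
    "severe_mental_illness": lambda p, c: 1.0 if p.severe_mental_illness else 0.0,
    "diet_unhealthy": lambda p, c: 1.0 if p.diet_unhealthy else 0.0,
    "pa_moderate": lambda p, c: 1.0 if p.physical_activity == "moderate" else 0.0,
    "pa_low": lambda p, c: 1.0 if p.physical_activity == "low" else 0.0,
    "pa_missing": lambda p, c: 1.0 if p.physical_activity == "missing" else 0.0,
    "townsend_step": lambda p, c: float(p.townsend_quintile - 1),
    "type1_diabetes": lambda p, c: 1.0 if p.diabetes_history == "type1" else 0.0,
    "pad_history": lambda p, c: 1.0 if "PAD" in p.cvd_history else 0.0,
    "other_chd_history": lambda p, c: 1.0 if "other_CHD" in p.cvd_history else 0.0,
}

# Indicator-valued time-updated covariates, resolved from DynamicState.
# Order fixed: the engine builds its per-cycle indicator matrix in this order.
DYNAMIC_INDICATORS = (
    "mi_this_year",
    "mi_prior_years",
    "stroke_this_year",
    "stroke_prior_years",
    "crv_any",
    "cancer_any",
    "diabetes_first_10y",
    "diabetes_after_10y",
)
DYNAMIC_INDEX = {name: i for i, name in enumerate(DYNAMIC_INDICATORS)}

# QoL models use the phase vocabulary of utility decrements; these alias the
# same indicators so one state produces one consistent covariate vector.
QOL_ALIASES = {
    "mi_year_of_event": "mi_this_year",
    "mi_subsequent": "mi_prior_years",
    "stroke_year_of_event": "stroke_this_year",
    "stroke_subsequent": "stroke_prior_years",
}

# Continuous dynamic covariates with special handling.
SPECIAL_DYNAMIC = ("hba1c_nondiabetic", "age_centred")


def dynamic_indicator_values(state) -> dict:
    """Current 0/1 value of every dynamic indicator for a DynamicState."""
    f = state.event_flags
    diab = f["diabetes"] != "never"
    return {
        "mi_this_year": 1.0 if f["mi"] == "this_year" else 0.0,
        "mi_prior_years": 1.0 if f["mi"] == "prior_years" else 0.0,
        "stroke_this_year": 1.0 if f["stroke"] == "this_year" else 0.0,
        "stroke_prior_years": 1.0 if f["stroke"] == "prior_years" else 0.0,
        "crv_any": 1.0 if f["crv"] != "never" else 0.0,
        "cancer_any": 1.0 if f["cancer"] != "never" else 0.0,
        "diabetes_first_10y": 1.0 if diab and state.diabetes_duration < 10 else 0.0,
        "diabetes_after_10y": 1.0 if diab and state.diabetes_duration >= 10 else 0.0,
    }


def resolve_covariate(name: str, profile, state, centring) -> float:
    """Value of a registry covariate for (profile, state).

    Raises CovariateError for names outside the registry.
    """
    from .errors import CovariateError

    if name in STATIC_COVARIATES:
        return STATIC_COVARIATES[name](profile, centring)
    canonical = QOL_ALIASES.get(name, name)
    if canonical in DYNAMIC_INDEX:
        return dynamic_indicator_values(state)[canonical]
    if name == "hba1c_nondiabetic":
        if state.event_flags["diabetes"] != "never":
            return 0.0
        return profile.hba1c - centring["hba1c"]
    if name == "age_centred":
        return state.current_age - centring["age"]
    raise CovariateError(f"unknown covariate {name!r} (registry v{REGISTRY_VERSION})")


def known_covariates() -> frozenset:
    """All names a coefficient map may legally use."""
    return frozenset(
        list(STATIC_COVARIATES)
        + list(DYNAMIC_INDICATORS)
        + list(QOL_ALIASES)
        + list(SPECIAL_DYNAMIC)
    )


def age_band(age: float, width: int = 5, lo: int = 40, hi: int = 70) -> str:
    """5-year entry-age band label, e.g. 56 -> '55-59'; ages >= hi -> '70+'."""
    if age >= hi:
        return f"{hi}+"
    if age < lo:
        return f"<{lo}"
    start = lo + width * int((age - lo) // width)
    return f"{start}-{start + width - 1}"
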
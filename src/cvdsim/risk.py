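"""Per-endpoint annual hazards under the Gompertz proportional-hazards model.

log h(age, x) = b0 + s0 + (b1 + s1) * (age - age_centre) + x'beta

with (b0, b1) the baseline intercept/age-slope, (s0, s1) additive
calibration shifts, and x the registry covariate vector built from a fixed
profile and the time-updated dynamic state. The annual cycle treats the
hazard as constant within the year, so the per-cycle event probability is
p = 1 - exp(-h).
"""

from __future__ import annotations

import math

from .coefficients import CoefficientSet, RiskEquation
from .errors import CVDSimError
from .profiles import DynamicState, IndividualProfile
from .registry import (DYNAMIC_INDEX, QOL_ALIASES, SPECIAL_DYNAMIC,
                       STATIC_COVARIATES, resolve_covariate)


def static_linear_predictor(profile: IndividualProfile, eq: RiskEquation,
                            centring: dict) -> float:
    """Contribution of entry-time covariates to the linear predictor."""
    total = 0.0
    for name, beta in eq.coefficients.items():
        if name in STATIC_COVARIATES:
            total += beta * STATIC_COVARIATES[name](profile, centring)
    return total


def dynamic_linear_predictor(profile: IndividualProfile, state: DynamicState,
                             eq: RiskEquation, centring: dict) -> float:
    """Contribution of time-updated covariates (event history, HbA1c switch)."""
    total = 0.0
    for name, beta in eq.coefficients.items():
        canonical = QOL_ALIASES.get(name, name)
        if canonical in DYNAMIC_INDEX or name in SPECIAL_DYNAMIC:
            total += beta * resolve_covariate(name, profile, state, centring)
    return total


def linear_predictor(profile: IndividualProfile, state: DynamicState,
                     eq: RiskEquation, centring: dict = None) -> float:
    """Full log-hazard-ratio sum x'beta for one person-state-equation."""
    from .registry import CENTRING_DEFAULTS
    c = centring if centring is not None else CENTRING_DEFAULTS
    # resolve every name (raises CovariateError for unknown keys)
    total = 0.0
    for name, beta in eq.coefficients.items():
        total += beta * resolve_covariate(name, profile, state, c)
    return total


def annual_hazard(profile: IndividualProfile, state: DynamicState,
                  eq: RiskEquation, centring: dict = None,
                  log_multiplier: float = 0.0) -> float:
    """Events/year hazard for one endpoint at the current state.

    `log_multiplier` carries treatment effects (log of the per-endpoint
    hazard multiplier), zero when untreated.
    """
    from .registry import CENTRING_DEFAULTS
    c = centring if centring is not None else CENTRING_DEFAULTS
    if not state.alive:
        raise CVDSimError("annual_hazard requires a living state")
    log_h = (eq.baseline.log_hazard_intercept + eq.calibration.intercept_shift
             + (eq.baseline.age_slope + eq.calibration.slope_shift)
             * (state.current_age - c["age"])
             + linear_predictor(profile, state, eq, c)
             + log_multiplier)
    h = math.exp(log_h)
    if not math.isfinite(h):
        raise CVDSimError(
            f"non-finite hazard for {eq.endpoint}/{eq.population} "
            f"(log hazard {log_h}); check the coefficient file")
    return h


def annual_event_probability(h: float) -> float:
    """Probability that a constant hazard h fires within a one-year cycle."""
    if h < 0:
        raise ValueError(f"hazard must be nonnegative, got {h}")
    return -math.expm1(-h)


def ten_year_mve_risk(profile: IndividualProfile, coefficients: CoefficientSet,
                      reps: int = 500, seed: int = 0) -> float:
    """Monte-Carlo 10-year risk (%) of a first major vascular event.

    A major vascular event is the first of MI, stroke, coronary
    revascularisation or vascular death; estimated by running the annual
    microsimulation over a 10-year horizon.
    """
    from .engine import SimulationConfig, run_microsimulation
    if reps < 1:
        raise ValueError("reps must be >= 1")
    config = SimulationConfig(replicates_per_person=reps, horizon_years=10,
                              master_seed=seed)
    summary = run_microsimulation([profile], coefficients, config)
    return float(summary.per_person["mve_10y"].iloc[0]) * 100.0
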
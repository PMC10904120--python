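"""Statin eligibility rules, treatment effects, and scenario contrasts.

Eligibility follows the UK guideline pattern: high-intensity statin
(atorvastatin 80 mg/day) for people with CVD history (20 mg when
eGFR < 60 mL/min/1.73m2), and atorvastatin 20 mg/day in primary
prevention for 10-year CVD risk >= 10%, type 1 diabetes, eGFR < 60, or
albuminuria.

Treatment translates into hazard modification through LDL lowering: the
regimen reduces LDL by a configured fraction of the baseline value, and
each affected vascular endpoint's hazard is multiplied by
rate_ratio_per_mmol ** delta_LDL. The effect sizes are required scenario
configuration — the package ships no clinical default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .coefficients import CoefficientSet
from .engine import SimulationConfig, run_microsimulation
from .errors import ConfigError
from .profiles import IndividualProfile
from .registry import ENDPOINT_INDEX, ENDPOINTS

REGIMENS = ("none", "atorva20", "atorva80")


@dataclass(frozen=True)
class StatinRule:
    """Deterministic eligibility and dosing rule."""
    ten_year_risk_threshold: float = 10.0   # percent
    egfr_threshold: float = 60.0            # mL/min/1.73m2

    def __post_init__(self):
        if self.ten_year_risk_threshold <= 0 or self.egfr_threshold <= 0:
            raise ConfigError("rule thresholds must be positive")


@dataclass(frozen=True)
class TreatmentEffect:
    """Statin effect configuration (user-supplied, no clinical defaults).

    ldl_reduction_fraction: fraction of baseline LDL removed, per regimen.
    rate_ratio_per_mmol: per-endpoint hazard ratio per 1 mmol/L LDL
    lowering, applied to the affected vascular endpoints only.
    """
    ldl_reduction_fraction: dict        # regimen -> fraction in [0, 1)
    rate_ratio_per_mmol: dict           # endpoint -> rate ratio in (0, 1]
    affected_endpoints: tuple = ("mi", "stroke", "crv", "vascular_death")

    def __post_init__(self):
        for regimen, frac in self.ldl_reduction_fraction.items():
            if regimen not in REGIMENS:
                raise ConfigError(f"unknown regimen {regimen!r}")
            if not 0.0 <= frac < 1.0:
                raise ConfigError(
                    f"ldl_reduction_fraction[{regimen}] must be in [0, 1)")
        for endpoint, rr in self.rate_ratio_per_mmol.items():
            if endpoint not in ENDPOINTS:
                raise ConfigError(f"unknown endpoint {endpoint!r}")
            if not 0.0 < rr <= 1.0:
                raise ConfigError(
                    f"rate_ratio_per_mmol[{endpoint}] must be in (0, 1]")
        for endpoint in self.affected_endpoints:
            if endpoint not in ENDPOINTS:
                raise ConfigError(f"unknown affected endpoint {endpoint!r}")


def assign_statin(profile: IndividualProfile, risk_percent: Optional[float],
                  rule: StatinRule) -> str:
    """Regimen for one person under the rule. Pure and deterministic."""
    egfr = profile.egfr_value()
    if profile.has_cvd_history:
        return "atorva20" if egfr < rule.egfr_threshold else "atorva80"
    qualifying = (profile.diabetes_history == "type1"
                  or egfr < rule.egfr_threshold
                  or bool(profile.albuminuria))
    if qualifying:
        return "atorva20"
    if risk_percent is None:
        raise ConfigError(
            f"person {profile.person_id}: primary-prevention eligibility "
            "needs a 10-year risk score (none supplied)")
    return "atorva20" if risk_percent >= rule.ten_year_risk_threshold else "none"


def apply_treatment(profile: IndividualProfile, regimen: str,
                    effect: TreatmentEffect) -> dict:
    """Per-endpoint hazard multipliers for one person on a regimen.

    delta_LDL = reduction fraction x baseline LDL; each affected endpoint
    gets multiplier rate_ratio ** delta_LDL; regimen 'none' is a no-op.
    Returns {'multipliers': {...}, 'ldl_reduction': float,
    'ldl_current': float}.
    """
    if regimen == "none":
        return {"multipliers": {e: 1.0 for e in effect.affected_endpoints},
                "ldl_reduction": 0.0, "ldl_current": profile.ldl}
    if regimen not in REGIMENS:
        raise ConfigError(f"unknown regimen {regimen!r}")
    frac = effect.ldl_reduction_fraction.get(regimen)
    if frac is None:
        raise ConfigError(f"effect config lacks ldl_reduction_fraction "
                          f"for {regimen!r}")
    delta = frac * profile.ldl
    multipliers = {}
    for endpoint in effect.affected_endpoints:
        rr = effect.rate_ratio_per_mmol.get(endpoint)
        if rr is None:
            raise ConfigError(f"effect config lacks rate_ratio_per_mmol "
                              f"for {endpoint!r}")
        multipliers[endpoint] = rr ** delta
    return {"multipliers": multipliers, "ldl_reduction": delta,
            "ldl_current": profile.ldl - delta}


@dataclass
class ScenarioResult:
    """Treated-vs-untreated contrast under common random numbers."""
    by_category: pd.DataFrame   # sex, age_band, quintile, n, fraction_eligible,
    #                             life_years_gained_per_1000, qalys_gained_per_1000
    eligibility: pd.Series      # per-person regimen
    treated_summary: object
    control_summary: object

    def overall(self) -> dict:
        df = self.by_category
        w = df["n"] / df["n"].sum()
        return {
            "life_years_gained_per_1000":
                float((df["life_years_gained_per_1000"] * w).sum()),
            "qalys_gained_per_1000":
                float((df["qalys_gained_per_1000"] * w).sum()),
            "fraction_eligible": float((df["fraction_eligible"] * w).sum()),
        }


def run_scenario(cohort, coefficients: CoefficientSet, rule: StatinRule,
                 effect: TreatmentEffect, uptake: dict,
                 config: SimulationConfig, seed: int = None) -> ScenarioResult:
    """Project gains from statin treatment vs a no-statin counterfactual.

    Eligibility is assessed once at entry from each profile's 10-year
    risk score. Per replicate, each eligible person initiates treatment
    with their deprivation quintile's uptake probability (1.0 everywhere
    = full coverage) and stays on it lifelong. Both arms run under common
    random numbers, so gains are exact per-person contrasts.
    """
    cohort = list(cohort)
    for q in range(1, 6):
        if q not in uptake:
            raise ConfigError(f"uptake map lacks quintile {q}")
    for q, u in uptake.items():
        if q not in (1, 2, 3, 4, 5):
            raise ConfigError(f"unknown quintile {q!r} in uptake map")
        if not 0.0 <= u <= 1.0:
            raise ConfigError(f"uptake[{q}]={u} outside [0, 1]")
    seed = config.master_seed if seed is None else seed
    n = len(cohort)
    regimens = [assign_statin(p, p.ten_year_cvd_risk, rule) for p in cohort]
    eligible = np.array([r != "none" for r in regimens])
    person_logmult = np.zeros((n, len(ENDPOINTS)))
    for i, (p, regimen) in enumerate(zip(cohort, regimens)):
        if regimen == "none":
            continue
        mult = apply_treatment(p, regimen, effect)["multipliers"]
        for endpoint, m in mult.items():
            person_logmult[i, ENDPOINT_INDEX[endpoint]] = math.log(m)
    uptake_p = np.array([uptake[p.townsend_quintile] for p in cohort])

    def treated_multipliers(rep):
        ss = np.random.SeedSequence(seed, spawn_key=(1, rep))
        u = np.random.Generator(np.random.PCG64(ss)).random(n)
        on_statin = eligible & (u < uptake_p)
        return person_logmult * on_statin[:, None]

    cfg = SimulationConfig(**{**config.__dict__, "master_seed": seed})
    treated = run_microsimulation(cohort, coefficients, cfg,
                                  multiplier_fn=treated_multipliers)
    control = run_microsimulation(cohort, coefficients, cfg)
    tp = treated.per_person
    cp = control.per_person
    delta = pd.DataFrame({
        "sex": tp["sex"], "age_band": tp["age_band"],
        "quintile": tp["townsend_quintile"],
        "eligible": eligible,
        "d_ly": tp["life_years"] - cp["life_years"],
        "d_qaly": tp["qalys"] - cp["qalys"],
    })
    grouped = delta.groupby(["sex", "age_band", "quintile"], observed=True)
    by_category = grouped.agg(
        n=("d_ly", "size"),
        fraction_eligible=("eligible", "mean"),
        life_years_gained_per_1000=("d_ly", lambda s: 1000.0 * s.mean()),
        qalys_gained_per_1000=("d_qaly", lambda s: 1000.0 * s.mean()),
    ).reset_index()
    return ScenarioResult(
        by_category=by_category,
        eligibility=pd.Series(regimens, index=[p.person_id for p in cohort]),
        treated_summary=treated, control_summary=control)
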
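"""Model-object front end.

`CVDMicrosimulation` bundles a cohort with a coefficient set the way a
statsmodels model bundles data with a design: `.simulate()` runs the
microsimulation and returns a results object carrying the per-person
outcomes, aggregates and a `summary()` table; `.psa()` and `.scenario()`
hang off the same object. `GompertzPHRegression` wraps risk-equation
estimation the same way (`.fit()` -> results with params, bse, summary).
"""

from __future__ import annotations

from typing import Optional, Sequence

from .coefficients import CoefficientSet, ReferencePopulation
from .engine import (PSAResult, SimulationConfig, SimulationSummary,
                     run_microsimulation, run_psa)
from .estimation import FollowUpRecords, GompertzPHResults, fit_risk_equation
from .population import gradient_gap, standardize, summarize_by_category
from .treatment import ScenarioResult, StatinRule, TreatmentEffect, run_scenario


class MicrosimulationResults:
    """Results of a cohort microsimulation run."""

    def __init__(self, summary: SimulationSummary, model: "CVDMicrosimulation"):
        self._summary = summary
        self.model = model
        self.per_person = summary.per_person
        self.n_replicates = summary.n_replicates

    def aggregate(self) -> dict:
        return self._summary.aggregate()

    def summary(self) -> str:
        return self._summary.summary()

    def by_category(self, categories: Sequence[str] = ("sex", "age_band"),
                    metrics=("life_years", "qalys")):
        return summarize_by_category(self.per_person, categories, metrics)

    def standardized(self, reference: ReferencePopulation,
                     metrics=("life_years", "qalys"),
                     margins: Optional[Sequence[str]] = None,
                     missing_policy: str = "error"):
        cells = summarize_by_category(
            self.per_person, ("sex", "age_band", "townsend_quintile"), metrics)
        return standardize(cells, reference, metrics, margins, missing_policy)

    def deprivation_gap(self, reference: ReferencePopulation,
                        metrics=("life_years", "qalys")):
        per_quintile = self.standardized(reference, metrics,
                                         margins=("quintile",),
                                         missing_policy="drop")
        return gradient_gap(per_quintile, metrics)


class CVDMicrosimulation:
    """The microsimulation policy model for a cohort + coefficient set."""

    def __init__(self, cohort, coefficients: CoefficientSet):
        self.cohort = list(cohort)
        self.coefficients = coefficients

    @classmethod
    def from_files(cls, cohort_path, coefficients_path) -> "CVDMicrosimulation":
        from .coefficients import read_coefficients
        from .profiles import read_cohort
        return cls(read_cohort(cohort_path),
                   read_coefficients(coefficients_path))

    def simulate(self, config: SimulationConfig = None,
                 **kwargs) -> MicrosimulationResults:
        cfg = config or SimulationConfig(**kwargs)
        return MicrosimulationResults(
            run_microsimulation(self.cohort, self.coefficients, cfg), self)

    def psa(self, ensemble, config: SimulationConfig = None,
            **kwargs) -> PSAResult:
        cfg = config or SimulationConfig(**kwargs)
        return run_psa(self.cohort, list(ensemble), cfg)

    def scenario(self, rule: StatinRule, effect: TreatmentEffect,
                 uptake: dict, config: SimulationConfig = None,
                 seed: int = None, **kwargs) -> ScenarioResult:
        cfg = config or SimulationConfig(**kwargs)
        return run_scenario(self.cohort, self.coefficients, rule, effect,
                            uptake, cfg, seed)


class GompertzPHRegression:
    """Gompertz proportional-hazards regression on follow-up data."""

    def __init__(self, ipd: FollowUpRecords, endpoint: str,
                 population: str, covariates: Sequence[str],
                 centring: dict = None):
        self.ipd = ipd
        self.endpoint = endpoint
        self.population = population
        self.covariates = list(covariates)
        self.centring = centring

    def fit(self) -> GompertzPHResults:
        return fit_risk_equation(self.ipd, self.endpoint, self.population,
                                 self.covariates, self.centring)
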
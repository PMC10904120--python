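import math

import pytest
from hypothesis import HealthCheck, settings

from cvdsim.coefficients import (Baseline, CoefficientSet, QoLModel,
                                 RiskEquation)
from cvdsim.registry import ENDPOINTS, POOLED_ENDPOINTS
from cvdsim.synthetic import (fixture_coefficient_set, generate_cohort,
                              typical_profile)

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def make_coefficient_set(rates=None, slopes=None, coefficients=None,
                         qol_intercept=1.0, qol_coefficients=None,
                         replicate_id=0) -> CoefficientSet:
    """Minimal complete coefficient set with controllable hazards.

    rates: endpoint -> events/year at the reference (default 0, i.e. a
    tiny floor hazard of exp(-30)); slopes/coefficients keyed the same.
    One equation per endpoint: pooled for cancer/diabetes, duplicated
    across no_cvd/cvd otherwise.
    """
    rates = rates or {}
    slopes = slopes or {}
    coefficients = coefficients or {}
    equations = {}
    for endpoint in ENDPOINTS:
        rate = rates.get(endpoint, 0.0)
        log_rate = math.log(rate) if rate > 0 else -30.0
        populations = (("pooled",) if endpoint in POOLED_ENDPOINTS
                       else ("no_cvd", "cvd"))
        for population in populations:
            equations[(endpoint, population)] = RiskEquation(
                endpoint=endpoint, population=population,
                baseline=Baseline(log_hazard_intercept=log_rate,
                                  age_slope=slopes.get(endpoint, 0.0)),
                coefficients=dict(coefficients.get(endpoint, {})))
    qol = QoLModel(intercept=qol_intercept,
                   coefficients=dict(qol_coefficients or {}))
    return CoefficientSet(equations=equations, qol=qol,
                          replicate_id=replicate_id)


@pytest.fixture(scope="session")
def fixture_cs():
    return fixture_coefficient_set()


@pytest.fixture(scope="session")
def typical():
    return typical_profile()


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(60, seed=1234)
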
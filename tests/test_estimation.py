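"""Risk-equation fitting, bootstrap, observed incidence, calibration,
validation."""

import math

import numpy as np
import pandas as pd
import pytest

from cvdsim.coefficients import Baseline, serialize
from cvdsim.errors import EstimationError
from cvdsim.estimation import (FitSpec, FollowUpRecords, bootstrap_ensemble,
                               build_episodes, calibrate, fit_risk_equation,
                               observed_cumulative_incidence, read_followup,
                               validate, write_followup)
from cvdsim.synthetic import generate_cohort, generate_followup
from conftest import make_coefficient_set

COVARIATES = ("male", "smoking_current", "ldl", "sbp")
TRUE_BETA = {"male": 0.5, "smoking_current": 0.6, "ldl": 0.25, "sbp": 0.01}


@pytest.fixture(scope="module")
def recovery_ipd():
    """Follow-up sampled from a single-event-plus-mortality model with
    known effects (true MI beta = 0.5 on male, etc.)."""
    cs = make_coefficient_set(
        rates={"mi": 0.008, "nonvascular_death": 0.01},
        slopes={"mi": 0.06, "nonvascular_death": 0.09},
        coefficients={"mi": dict(TRUE_BETA)})
    cohort = generate_cohort(5000, seed=31)
    return cs, generate_followup(cohort, cs, max_years=10.0, seed=32)


class TestFitRiskEquation:
    def test_parameter_recovery_within_three_se(self, recovery_ipd):
        cs, ipd = recovery_ipd
        res = fit_risk_equation(ipd, "mi", "no_cvd", COVARIATES)
        for name, true in TRUE_BETA.items():
            err = abs(res.equation.coefficients[name] - true)
            assert err < 3 * res.bse[name], name
        true_eq = cs.equation("mi", "no_cvd")
        assert abs(res.equation.baseline.log_hazard_intercept
                   - true_eq.baseline.log_hazard_intercept) \
            < 3 * res.bse["intercept"]
        assert abs(res.equation.baseline.age_slope
                   - true_eq.baseline.age_slope) < 3 * res.bse["age_slope"]

    def test_null_model_recovers_crude_rate(self):
        cs = make_coefficient_set(rates={"nonvascular_death": 0.03})
        cohort = generate_cohort(3000, seed=33)
        ipd = generate_followup(cohort, cs, max_years=8.0, seed=34)
        res = fit_risk_equation(ipd, "nonvascular_death", "no_cvd", [])
        episodes = build_episodes(ipd, "nonvascular_death", [], "no_cvd")
        crude = math.log(episodes.event.sum() / episodes.exposure.sum())
        # age slope ~0 here, so the intercept is the crude log rate
        assert abs(res.equation.baseline.log_hazard_intercept - crude) \
            < 3 * res.bse["intercept"] + 0.05

    def test_constant_covariate_dropped_and_flagged(self, recovery_ipd):
        _, ipd = recovery_ipd
        with pytest.warns(UserWarning, match="pad_history"):
            res = fit_risk_equation(ipd, "mi", "no_cvd",
                                    ["male", "pad_history"])
        assert "pad_history" in res.dropped
        assert "pad_history" not in res.equation.coefficients

    def test_no_events_raises(self):
        cs = make_coefficient_set(rates={"nonvascular_death": 0.02})
        cohort = generate_cohort(200, seed=35)
        ipd = generate_followup(cohort, cs, max_years=5.0, seed=36)
        with pytest.raises(EstimationError, match="mi"):
            fit_risk_equation(ipd, "mi", "no_cvd", [])

    def test_matches_statsmodels_glm_oracle(self, recovery_ipd):
        """Independent cross-check: same episode likelihood maximised by
        statsmodels Poisson GLM."""
        import statsmodels.api as sm
        _, ipd = recovery_ipd
        res = fit_risk_equation(ipd, "mi", "no_cvd", ["male", "ldl"])
        episodes = build_episodes(ipd, "mi", ["male", "ldl"], "no_cvd")
        X = np.column_stack([np.ones(len(episodes)),
                             episodes.age - 60.0,
                             episodes.male, episodes.ldl])
        glm = sm.GLM(episodes.event, X, family=sm.families.Poisson(),
                     offset=np.log(episodes.exposure)).fit()
        ours = [res.equation.baseline.log_hazard_intercept,
                res.equation.baseline.age_slope,
                res.equation.coefficients["male"],
                res.equation.coefficients["ldl"]]
        assert np.allclose(ours, glm.params, atol=1e-6)


class TestBootstrap:
    def test_deterministic_given_seed(self, recovery_ipd):
        cs, ipd = recovery_ipd
        specs = [FitSpec("mi", "no_cvd", ("male",))]
        a = bootstrap_ensemble(ipd, specs, B=5, seed=77, base_set=cs)
        b = bootstrap_ensemble(ipd, specs, B=5, seed=77, base_set=cs)
        assert [serialize(x) for x in a] == [serialize(y) for y in b]
        assert [x.replicate_id for x in a] == [1, 2, 3, 4, 5]

    def test_requested_size(self, recovery_ipd):
        cs, ipd = recovery_ipd
        specs = [FitSpec("mi", "no_cvd", ("male",))]
        ensemble = bootstrap_ensemble(ipd, specs, B=12, seed=78, base_set=cs)
        assert len(ensemble) == 12

    def test_spread_brackets_model_se(self, recovery_ipd):
        """Bootstrap SD of a coefficient should be near the model SE."""
        cs, ipd = recovery_ipd
        specs = [FitSpec("mi", "no_cvd", ("male",))]
        res = fit_risk_equation(ipd, "mi", "no_cvd", ["male"])
        ensemble = bootstrap_ensemble(ipd, specs, B=60, seed=79, base_set=cs)
        draws = [e.equations[("mi", "no_cvd")].coefficients["male"]
                 for e in ensemble]
        ratio = np.std(draws) / res.bse["male"]
        assert 0.5 < ratio < 2.0


class TestObservedCumulativeIncidence:
    def _records(self, rows, censor, max_years=5.0):
        cohort = generate_cohort(len(censor), seed=40)
        events = pd.DataFrame(rows, columns=["person_id", "endpoint", "time"])
        ct = {p.person_id: censor[i] for i, p in enumerate(cohort)}
        return FollowUpRecords(cohort, events, ct, max_years)

    def test_hand_computed_curve_no_competing(self):
        cohort = generate_cohort(4, seed=41)
        ids = [p.person_id for p in cohort]
        rows = [(ids[0], "mi", 0.5), (ids[1], "mi", 1.5)]
        ipd = FollowUpRecords(
            cohort, pd.DataFrame(rows, columns=["person_id", "endpoint",
                                                "time"]),
            {ids[0]: 5.0, ids[1]: 5.0, ids[2]: 3.0, ids[3]: 4.0}, 5.0)
        curve = observed_cumulative_incidence(ipd, "mi", horizon=2)
        assert curve.loc[1] == pytest.approx(0.25)
        assert curve.loc[2] == pytest.approx(0.50)
        km = observed_cumulative_incidence(ipd, "mi", horizon=2,
                                           competing_risks=False)
        assert np.allclose(km.to_numpy(), curve.to_numpy())

    def test_no_events_flat_zero(self):
        ipd = self._records([], [5.0, 5.0, 5.0])
        assert (observed_cumulative_incidence(ipd, "stroke", 5) == 0).all()

    def test_all_events_first_year_jump_to_one(self):
        cohort = generate_cohort(3, seed=42)
        rows = [(p.person_id, "mi", 0.2 + 0.1 * i)
                for i, p in enumerate(cohort)]
        ipd = FollowUpRecords(
            cohort, pd.DataFrame(rows, columns=["person_id", "endpoint",
                                                "time"]),
            {p.person_id: 5.0 for p in cohort}, 5.0)
        curve = observed_cumulative_incidence(ipd, "mi", 3)
        assert curve.loc[1] == pytest.approx(1.0)

    def test_competing_death_lowers_incidence_vs_km(self):
        cs = make_coefficient_set(rates={"mi": 0.03,
                                         "nonvascular_death": 0.08})
        cohort = generate_cohort(2000, seed=43)
        ipd = generate_followup(cohort, cs, max_years=10.0, seed=44)
        aj = observed_cumulative_incidence(ipd, "mi", 10)
        km = observed_cumulative_incidence(ipd, "mi", 10,
                                           competing_risks=False)
        assert aj.loc[10] < km.loc[10]

    def test_followup_csv_round_trip(self, tmp_path):
        cs = make_coefficient_set(rates={"mi": 0.05,
                                         "vascular_death": 0.02})
        cohort = generate_cohort(100, seed=45)
        ipd = generate_followup(cohort, cs, max_years=5.0, seed=46)
        path = tmp_path / "ipd.csv"
        write_followup(ipd, path)
        back = read_followup(path, cohort)
        merged = ipd.events.sort_values(["person_id", "time"]).reset_index(drop=True)
        merged2 = back.events.sort_values(["person_id", "time"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(merged, merged2)
        assert back.censor_time == pytest.approx(ipd.censor_time)


@pytest.fixture(scope="module")
def base_and_target():
    cs = make_coefficient_set(
        rates={"mi": 0.006, "stroke": 0.004, "cancer": 0.006,
               "vascular_death": 0.003, "nonvascular_death": 0.008},
        slopes={"vascular_death": 0.08, "nonvascular_death": 0.08})
    cohort = generate_cohort(6000, seed=51)
    return cs, cohort


class TestCalibrate:

    @staticmethod
    def _events(ipd, endpoint, population):
        return build_episodes(ipd, endpoint, [], population).event.sum()

    def test_self_calibration_is_near_fixed_point(self, base_and_target):
        cs, cohort = base_and_target
        ipd = generate_followup(cohort, cs, max_years=8.0, seed=52)
        _, reports = calibrate(cs, ipd, horizon=8,
                               endpoints=["mi", "nonvascular_death"])
        for r in reports:
            # the shift estimate's MC noise scales as 1/sqrt(events)
            tol = 3.0 / math.sqrt(self._events(ipd, r.endpoint, r.population))
            assert abs(r.intercept_shift) < tol, r.endpoint

    def test_doubled_hazards_recovered_as_log2_shift(self, base_and_target):
        cs, cohort = base_and_target
        doubled = cs.copy()
        for eq in doubled.equations.values():
            eq.baseline = Baseline(
                eq.baseline.log_hazard_intercept + math.log(2),
                eq.baseline.age_slope)
        ipd = generate_followup(cohort, doubled, max_years=8.0, seed=53)
        _, reports = calibrate(cs, ipd, horizon=8,
                               endpoints=["mi", "nonvascular_death"])
        for r in reports:
            tol = 3.0 / math.sqrt(self._events(ipd, r.endpoint, r.population))
            assert abs(r.intercept_shift - math.log(2)) < tol, r.endpoint

    def test_objective_never_worsens(self, base_and_target):
        cs, cohort = base_and_target
        ipd = generate_followup(cohort, cs, max_years=8.0, seed=54)
        _, reports = calibrate(cs, ipd, horizon=8)
        for r in reports:
            assert r.objective_post <= r.objective_pre + 1e-12


class TestValidate:
    def test_self_consistency_ratios_near_one(self):
        cs = make_coefficient_set(
            rates={"mi": 0.01, "nonvascular_death": 0.015},
            slopes={"nonvascular_death": 0.07})
        cohort = generate_cohort(8000, seed=61)
        ipd = generate_followup(cohort, cs, max_years=8.0, seed=62)
        report = validate(cs, ipd, replicates=5, seed=63)
        tbl = report.table
        # ratio noise ~ 1/sqrt(observed events): check cells where that
        # noise is below ~7%, and the overall mean ratio tightly
        busy = tbl[(tbl.n_events >= 200)]
        assert len(busy) > 0
        assert ((busy.ratio > 0.85) & (busy.ratio < 1.15)).all()
        assert tbl[tbl.n_events >= 50].ratio.mean() == pytest.approx(1.0,
                                                                     abs=0.08)

    def test_partition_additivity_of_event_counts(self):
        cs = make_coefficient_set(rates={"mi": 0.02,
                                         "nonvascular_death": 0.02})
        cohort = generate_cohort(800, seed=64)
        ipd = generate_followup(cohort, cs, max_years=5.0, seed=65)
        report = validate(
            cs, ipd, replicates=2, seed=66,
            subgroups={"men": lambda p: p.sex == "male",
                       "women": lambda p: p.sex == "female"})
        whole = validate(cs, ipd, replicates=2, seed=66)
        t = report.table
        w = whole.table
        for year in (1, 3, 5):
            parts = t[(t.endpoint == "mi") & (t.year == year)].n_events.sum()
            total = w[(w.endpoint == "mi") & (w.year == year)].n_events.sum()
            assert parts == total

    def test_per_endpoint_horizon_limits_rows(self):
        cs = make_coefficient_set(rates={"mi": 0.02, "diabetes": 0.02,
                                         "nonvascular_death": 0.02})
        cohort = generate_cohort(300, seed=67)
        ipd = generate_followup(cohort, cs, max_years=12.0, seed=68)
        report = validate(cs, ipd, replicates=2, seed=69,
                          default_horizon=12, horizons={"diabetes": 8})
        tbl = report.table
        assert tbl[tbl.endpoint == "diabetes"].year.max() == 8
        assert tbl[tbl.endpoint == "mi"].year.max() == 12

    def test_empty_subgroup_reported_as_skipped(self):
        cs = make_coefficient_set(rates={"nonvascular_death": 0.02})
        cohort = generate_cohort(100, seed=70)
        ipd = generate_followup(cohort, cs, max_years=3.0, seed=71)
        report = validate(cs, ipd, replicates=1, seed=72,
                          subgroups={"all": lambda p: True,
                                     "nobody": lambda p: False})
        assert report.skipped == ["nobody"]
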
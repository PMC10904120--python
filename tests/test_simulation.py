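"""Annual-cycle microsimulation mechanics and invariants."""

import math

import numpy as np
import pytest

from cvdsim.engine import (SimulationConfig, _replicate_rng,
                           run_microsimulation, run_psa, simulate_cycle,
                           simulate_individual)
from cvdsim.profiles import initial_state
from cvdsim.registry import ENDPOINTS
from cvdsim.synthetic import generate_cohort, typical_profile
from conftest import make_coefficient_set


class TestSimulateCycle:
    def test_zero_hazards_no_events_and_aging(self, typical):
        cs = make_coefficient_set()
        state = initial_state(typical)
        fired = simulate_cycle(typical, state, cs, _replicate_rng(0, 0))
        assert fired == []
        assert state.alive
        state.roll_cycle()
        assert state.current_age == typical.age_entry + 1

    def test_saturating_death_hazard_aborts_cycle(self, typical):
        cs = make_coefficient_set(rates={"nonvascular_death": 1e9,
                                         "mi": 1e9})
        deaths = 0
        for rep in range(50):
            state = initial_state(typical)
            fired = simulate_cycle(typical, state, cs, _replicate_rng(1, rep))
            if not state.alive:
                deaths += 1
                assert state.cause_of_death in ("vascular", "nonvascular")
                death_pos = [e for e in fired].index(
                    "nonvascular_death") if "nonvascular_death" in fired else None
                if death_pos is not None:
                    # nothing fires after the death
                    assert death_pos == len(fired) - 1
        assert deaths == 50

    def test_first_occurrences_only(self, typical):
        cs = make_coefficient_set(rates={"mi": 1e9})
        state = initial_state(typical)
        rng = _replicate_rng(2, 0)
        assert simulate_cycle(typical, state, cs, rng) == ["mi"]
        state.roll_cycle()
        assert simulate_cycle(typical, state, cs, rng) == []

    def test_small_hazard_marginals_match_continuous_oracle(self, typical):
        """Per-cycle marginal event probabilities vs the independent
        exponential-competing-times oracle, all hazards small."""
        hazards = {"mi": 0.02, "stroke": 0.015, "nonvascular_death": 0.01}
        cs = make_coefficient_set(rates=hazards)
        n = 60_000
        rng = _replicate_rng(3, 0)
        counts = {e: 0 for e in hazards}
        for _ in range(n):
            state = initial_state(typical)
            for e in simulate_cycle(typical, state, cs, rng):
                counts[e] += 1
        total = sum(hazards.values())
        for e, h in hazards.items():
            # continuous-time competing-risks one-year marginal
            expected = (h / total) * (1 - math.exp(-total))
            se = math.sqrt(expected * (1 - expected) / n)
            assert abs(counts[e] / n - expected) < 2.5 * se, e


class TestSimulateIndividual:
    def test_age_cap_arithmetic_with_zero_hazards(self):
        import dataclasses
        p = dataclasses.replace(typical_profile(), age_entry=60.0)
        cs = make_coefficient_set(qol_intercept=1.0)
        config = SimulationConfig(replicates_per_person=1)
        traj = simulate_individual(p, cs, config, _replicate_rng(4, 0))
        assert traj.death_year is None
        assert traj.cause_of_death == "none"
        assert traj.life_years == pytest.approx(50.0)
        assert traj.qalys == pytest.approx(50.0)

    def test_constant_mortality_mean_life_years(self):
        """Discrete annual survival with hazard h: E[complete years] =
        q/(1-q)... checked against the exact geometric formula plus the
        half-cycle half year."""
        import dataclasses
        p = dataclasses.replace(typical_profile(), age_entry=40.0)
        h = 0.05
        cs = make_coefficient_set(rates={"nonvascular_death": h})
        config = SimulationConfig(replicates_per_person=1,
                                  half_cycle_correction=True)
        n = 4000
        lys = [simulate_individual(p, cs, config, _replicate_rng(5, r)).life_years
               for r in range(n)]
        q = 1 - math.exp(-h)   # annual death probability
        # complete years ~ Geometric; censoring at 110 negligible here
        expected = (1 - q) / q + 0.5
        se = np.std(lys) / math.sqrt(n)
        assert abs(np.mean(lys) - expected) < 3 * se

    def test_huge_event_history_effect_kills_quickly(self, typical):
        cs = make_coefficient_set(
            rates={"mi": 0.2, "vascular_death": 1e-4},
            coefficients={"vascular_death": {"mi_this_year": 9.0,
                                             "mi_prior_years": 9.0}})
        config = SimulationConfig(replicates_per_person=1)
        gaps = []
        for r in range(300):
            traj = simulate_individual(typical, cs, config,
                                       _replicate_rng(6, r))
            if traj.event_years["mi"] is not None and traj.death_year is not None:
                gaps.append(traj.death_year - traj.event_years["mi"])
        assert len(gaps) > 100
        assert np.median(gaps) <= 2

    def test_qaly_bounds_respect_eq5d_range(self, typical):
        cs = make_coefficient_set(
            rates={"mi": 0.3, "stroke": 0.3, "nonvascular_death": 0.05},
            qol_intercept=-0.2,
            qol_coefficients={"mi_subsequent": -0.9, "stroke_subsequent": -0.9})
        config = SimulationConfig(replicates_per_person=1)
        for r in range(50):
            traj = simulate_individual(typical, cs, config,
                                       _replicate_rng(7, r))
            assert traj.qalys <= traj.life_years * 1.0 + 1e-12
            assert traj.qalys >= traj.life_years * -0.594 - 1e-12
            for u in traj.utilities:
                assert -0.594 <= u <= 1.0

    def test_accounting_identity_from_audit_stream(self, typical, fixture_cs):
        config = SimulationConfig(replicates_per_person=1)
        traj = simulate_individual(typical, fixture_cs, config,
                                   _replicate_rng(8, 3))
        n_cycles = len(traj.utilities)
        if traj.death_year is not None:
            expected_ly = (n_cycles - 1) + 0.5
            expected_qaly = sum(traj.utilities[:-1]) + 0.5 * traj.utilities[-1]
        else:
            expected_ly = n_cycles
            expected_qaly = sum(traj.utilities)
        assert traj.life_years == pytest.approx(expected_ly)
        assert traj.qalys == pytest.approx(expected_qaly)


class TestRunMicrosimulation:
    def test_bitwise_determinism(self, small_cohort, fixture_cs):
        config = SimulationConfig(replicates_per_person=3, master_seed=99)
        a = run_microsimulation(small_cohort, fixture_cs, config)
        b = run_microsimulation(small_cohort, fixture_cs, config)
        assert a.per_person.equals(b.per_person)

    def test_scalar_and_vector_paths_identical_for_one_person(self, typical,
                                                              fixture_cs):
        config = SimulationConfig(replicates_per_person=1, master_seed=42)
        traj = simulate_individual(typical, fixture_cs, config,
                                   _replicate_rng(42, 0))
        summary = run_microsimulation([typical], fixture_cs, config)
        row = summary.per_person.iloc[0]
        assert row.life_years == pytest.approx(traj.life_years)
        assert row.qalys == pytest.approx(traj.qalys)
        for e in ENDPOINTS:
            fired = traj.event_years[e] is not None
            assert bool(row[f"ci_{e}_life"]) == fired

    def test_identical_twins_agree_within_mc_error(self, fixture_cs):
        import dataclasses
        p = typical_profile()
        twin = dataclasses.replace(p, person_id="twin")
        config = SimulationConfig(replicates_per_person=400, master_seed=17)
        summary = run_microsimulation([p, twin], fixture_cs, config)
        ly = summary.per_person.life_years
        sd = 8.0  # lifetime SD of a single replicate is < 8 years here
        se = sd * math.sqrt(2.0 / 400)
        assert abs(ly.iloc[0] - ly.iloc[1]) < 3 * se

    def test_exactly_one_death_or_censoring(self, small_cohort, fixture_cs):
        config = SimulationConfig(replicates_per_person=4, master_seed=5)
        summary = run_microsimulation(small_cohort, fixture_cs, config)
        total = (summary.per_person.death_vascular
                 + summary.per_person.death_nonvascular
                 + summary.per_person.censored_alive)
        assert np.allclose(total, 1.0)

    def test_mc_error_scales_with_replicates(self, typical, fixture_cs):
        """Doubling replicates shrinks the seed-to-seed SD of the mean
        life years by about sqrt(2)."""
        def spread(reps):
            means = []
            for seed in range(12):
                config = SimulationConfig(replicates_per_person=reps,
                                          master_seed=1000 + seed)
                s = run_microsimulation([typical], fixture_cs, config)
                means.append(float(s.per_person.life_years.iloc[0]))
            return np.std(means)

        ratio = spread(25) / spread(100)
        assert 2.0 * 0.6 < ratio ** 2 < 4.0 * 1.4   # var ratio ~ 4

    def test_fixed_event_orders_bracket_random_order(self, typical):
        """With small hazards, per-endpoint lifetime incidence under two
        opposite fixed orderings agrees within MC tolerance."""
        rates = {"mi": 0.03, "vascular_death": 0.02,
                 "nonvascular_death": 0.03}
        cs = make_coefficient_set(rates=rates)
        results = {}
        for name, order in (("fwd", tuple(ENDPOINTS)),
                            ("rev", tuple(reversed(ENDPOINTS)))):
            config = SimulationConfig(replicates_per_person=800,
                                      master_seed=3, event_order=order)
            s = run_microsimulation([typical], cs, config)
            results[name] = s.per_person["ci_mi_life"].iloc[0]
        # ~0.43 incidence; binomial SE at 800 reps
        se = math.sqrt(0.45 * 0.55 / 800)
        assert abs(results["fwd"] - results["rev"]) < 3 * se


class TestRunPSA:
    def test_identical_sets_give_zero_width_intervals(self, typical):
        cs = make_coefficient_set(rates={"nonvascular_death": 0.03})
        ensemble = [make_coefficient_set(rates={"nonvascular_death": 0.03},
                                         replicate_id=k)
                    for k in range(1, 6)]
        config = SimulationConfig(replicates_per_person=10, master_seed=0)
        result = run_psa([typical], [cs] + ensemble, config)
        iv = result.intervals.set_index("metric")
        assert iv.loc["mean_life_years", "lo"] == pytest.approx(
            iv.loc["mean_life_years", "hi"])

    def test_interval_width_grows_with_jitter(self, typical):
        widths = []
        for sd in (0.02, 0.1, 0.3):
            rng = np.random.default_rng(5)
            ensemble = []
            for k in range(1, 25):
                cs = make_coefficient_set(
                    rates={"nonvascular_death": 0.03 * math.exp(
                        rng.normal(0, sd))}, replicate_id=k)
                ensemble.append(cs)
            config = SimulationConfig(replicates_per_person=20, master_seed=0)
            result = run_psa([typical], ensemble, config)
            iv = result.intervals.set_index("metric")
            widths.append(float(iv.loc["mean_life_years", "hi"]
                                - iv.loc["mean_life_years", "lo"]))
        assert widths[0] < widths[1] < widths[2]

    def test_single_member_warns(self, typical):
        cs = make_coefficient_set(rates={"nonvascular_death": 0.05},
                                  replicate_id=1)
        config = SimulationConfig(replicates_per_person=5, master_seed=0)
        with pytest.warns(UserWarning, match="degenerate"):
            run_psa([typical], [cs], config)
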
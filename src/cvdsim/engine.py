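"""Annual-cycle competing-event microsimulation.

Each simulated year, the seven endpoints (first MI, stroke, coronary
revascularisation, incident cancer, incident diabetes, vascular death,
nonvascular death) are evaluated in a uniformly random order. An endpoint
fires with probability 1 - exp(-h) given its current annual hazard; by
default events fired earlier in the same cycle feed the hazards of later
draws (so a same-year MI raises same-year vascular-death risk). A death
aborts the remaining draws. Survivors age one year, year-of-event flags
roll to prior-years, and simulation continues until death, the 110-year
age cap, or a fixed horizon.

Randomness: per replicate, one PCG64 stream seeded from
SeedSequence(master_seed, spawn_key=(0, replicate)) supplies two uniform
matrices per cycle — one per (person, endpoint) for the event order, one
for the trigger draws, the trigger indexed by endpoint identity rather
than draw position. Draws are therefore a pure function of
(seed, replicate, cycle, person, endpoint), which makes runs bitwise
reproducible and gives common random numbers across treatment scenarios.

Two equivalent implementations share this draw discipline: a scalar
reference path (`simulate_cycle` / `simulate_individual`) and a
vectorized cohort path used by `run_microsimulation`; for a single person
they produce identical trajectories.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import registry, risk
from .coefficients import CoefficientSet
from .errors import ConfigError
from .profiles import DynamicState, IndividualProfile, initial_state
from .qol import predict_utility
from .registry import AGE_CAP, ENDPOINT_INDEX, ENDPOINTS

N_ENDPOINTS = len(ENDPOINTS)
_MVE_IDX = [ENDPOINT_INDEX[e] for e in ("mi", "stroke", "crv", "vascular_death")]


@dataclass
class SimulationConfig:
    """Settings for a microsimulation run.

    horizon_years None means lifetime (to death or age 110). 500
    replicates per person keep Monte Carlo noise small for per-person
    summaries; property tests use fewer.
    """

    replicates_per_person: int = 500
    horizon_years: Optional[int] = None
    master_seed: int = 0
    half_cycle_correction: bool = True
    discount_rate: float = 0.0
    within_cycle_updates: bool = True
    event_order: object = "random"        # "random" or fixed sequence of endpoints
    ci_years: Sequence[int] = (10, 20)    # horizons for cumulative incidence output

    def __post_init__(self):
        if self.replicates_per_person < 1:
            raise ConfigError("replicates_per_person must be >= 1")
        if self.horizon_years is not None and self.horizon_years < 1:
            raise ConfigError("horizon_years must be positive")
        if self.discount_rate < 0:
            raise ConfigError("discount_rate must be >= 0")
        if self.event_order != "random":
            order = tuple(self.event_order)
            if sorted(order) != sorted(ENDPOINTS):
                raise ConfigError(
                    "event_order must be 'random' or a permutation of all endpoints")


@dataclass
class Trajectory:
    """One simulated lifetime for one person."""
    person_id: str
    replicate_id: int
    event_years: dict                  # endpoint -> year index (entry year = 0) or None
    death_year: Optional[int]
    cause_of_death: str                # none / vascular / nonvascular
    life_years: float
    qalys: float
    utilities: list = field(default_factory=list)   # per-cycle audit stream


# ---------------------------------------------------------------------------
# scalar reference implementation


def _cycle_discount(config: SimulationConfig, cycle: int) -> float:
    if config.discount_rate == 0:
        return 1.0
    return (1.0 + config.discount_rate) ** -(cycle + 0.5)


def simulate_cycle(profile: IndividualProfile, state: DynamicState,
                   coefficients: CoefficientSet, rng,
                   config: SimulationConfig = None,
                   log_multipliers: dict = None):
    """Advance one annual cycle in place; return the endpoints fired.

    `log_multipliers` maps endpoint -> log hazard multiplier (treatment
    effects); missing endpoints default to 0 (no modification).
    """
    cfg = config or SimulationConfig(replicates_per_person=1)
    mult = log_multipliers or {}
    u_order = rng.random(N_ENDPOINTS)
    u_trig = rng.random(N_ENDPOINTS)
    if cfg.event_order == "random":
        order = np.argsort(u_order)
    else:
        order = [ENDPOINT_INDEX[e] for e in cfg.event_order]
    snapshot = None
    if not cfg.within_cycle_updates:
        snapshot = dataclasses.replace(
            state, event_flags=dict(state.event_flags),
            years_since=dict(state.years_since))
    fired = []
    for idx in order:
        endpoint = ENDPOINTS[idx]
        if not state.alive:
            break
        if endpoint in registry.EVENT_ENDPOINTS \
                and state.event_flags[endpoint] != "never":
            continue  # first occurrences only
        hazard_state = snapshot if snapshot is not None else state
        eq = coefficients.equation(endpoint, profile.population)
        h = risk.annual_hazard(profile, hazard_state, eq, coefficients.centring,
                               log_multiplier=mult.get(endpoint, 0.0))
        if u_trig[idx] < risk.annual_event_probability(h):
            fired.append(endpoint)
            if endpoint == "vascular_death":
                state.alive = False
                state.cause_of_death = "vascular"
            elif endpoint == "nonvascular_death":
                state.alive = False
                state.cause_of_death = "nonvascular"
            else:
                state.record_event(endpoint)
    return fired


def simulate_individual(profile: IndividualProfile,
                        coefficients: CoefficientSet,
                        config: SimulationConfig, rng,
                        replicate_id: int = 0,
                        log_multipliers: dict = None) -> Trajectory:
    """Simulate one full lifetime (or horizon) for one person."""
    state = initial_state(profile)
    event_years = {e: None for e in ENDPOINTS}
    life_years = 0.0
    qalys = 0.0
    utilities = []
    cycle = 0
    while state.alive and state.current_age < AGE_CAP \
            and (config.horizon_years is None or cycle < config.horizon_years):
        fired = simulate_cycle(profile, state, coefficients, rng,
                               config, log_multipliers)
        for endpoint in fired:
            event_years[endpoint] = cycle
        u = predict_utility(profile, state, coefficients.qol,
                            coefficients.centring)
        utilities.append(u)
        disc = _cycle_discount(config, cycle)
        if state.alive:
            life_years += disc
            qalys += u * disc
            state.roll_cycle()
        else:
            if config.half_cycle_correction:
                life_years += 0.5 * disc
                qalys += 0.5 * u * disc
        cycle += 1
    death_year = cycle - 1 if not state.alive else None
    return Trajectory(person_id=profile.person_id, replicate_id=replicate_id,
                      event_years=event_years, death_year=death_year,
                      cause_of_death=state.cause_of_death,
                      life_years=life_years, qalys=qalys, utilities=utilities)


# ---------------------------------------------------------------------------
# vectorized cohort engine


class _VectorEngine:
    """Precomputed array representation of cohort x coefficient set."""

    def __init__(self, profiles, coefficients: CoefficientSet,
                 config: SimulationConfig,
                 log_multipliers: Optional[np.ndarray] = None):
        self.profiles = list(profiles)
        self.cs = coefficients
        self.config = config
        n = self.n = len(self.profiles)
        if n == 0:
            raise ConfigError("cohort must be nonempty")
        c = coefficients.centring
        self.age_centre = c["age"]
        self.b0 = np.empty((n, N_ENDPOINTS))
        self.b1 = np.empty((n, N_ENDPOINTS))
        self.static_lp = np.empty((n, N_ENDPOINTS))
        self.hcoef = np.zeros((n, N_ENDPOINTS))
        nd = len(registry.DYNAMIC_INDICATORS)
        self.T = np.zeros((n, N_ENDPOINTS, nd))
        self.age0 = np.array([p.age_entry for p in self.profiles])
        self.hba1c_c = np.array([p.hba1c - c["hba1c"] for p in self.profiles])
        seen = {}   # repeated profile objects share one precomputed row
        for i, p in enumerate(self.profiles):
            j0 = seen.get(id(p))
            if j0 is not None:
                self.b0[i] = self.b0[j0]
                self.b1[i] = self.b1[j0]
                self.static_lp[i] = self.static_lp[j0]
                self.hcoef[i] = self.hcoef[j0]
                self.T[i] = self.T[j0]
                continue
            seen[id(p)] = i
            for j, endpoint in enumerate(ENDPOINTS):
                eq = coefficients.equation(endpoint, p.population)
                self.b0[i, j] = (eq.baseline.log_hazard_intercept
                                 + eq.calibration.intercept_shift)
                self.b1[i, j] = eq.baseline.age_slope + eq.calibration.slope_shift
                self.static_lp[i, j] = risk.static_linear_predictor(p, eq, c)
                for name, beta in eq.coefficients.items():
                    canonical = registry.QOL_ALIASES.get(name, name)
                    if canonical in registry.DYNAMIC_INDEX:
                        self.T[i, j, registry.DYNAMIC_INDEX[canonical]] += beta
                    elif name == "hba1c_nondiabetic":
                        self.hcoef[i, j] = beta
        self.logmult = (np.zeros((n, N_ENDPOINTS)) if log_multipliers is None
                        else np.asarray(log_multipliers, dtype=float))
        if self.logmult.shape != (n, N_ENDPOINTS):
            raise ConfigError("log_multipliers must have shape (n_persons, 7)")
        # QoL decomposition
        qol = coefficients.qol
        self.q_bounds = qol.bounds
        self.q_dyn = np.zeros(nd)
        self.q_hba1c = 0.0
        self.q_age = 0.0
        q_static = np.full(n, qol.intercept)
        for name, beta in qol.coefficients.items():
            canonical = registry.QOL_ALIASES.get(name, name)
            if canonical in registry.DYNAMIC_INDEX:
                self.q_dyn[registry.DYNAMIC_INDEX[canonical]] += beta
            elif name == "hba1c_nondiabetic":
                self.q_hba1c = beta
            elif name == "age_centred":
                self.q_age = beta
            else:
                for i, p in enumerate(self.profiles):
                    q_static[i] += beta * registry.STATIC_COVARIATES[name](p, c)
        self.q_static = q_static
        if config.event_order == "random":
            self.fixed_order = None
        else:
            self.fixed_order = np.array(
                [ENDPOINT_INDEX[e] for e in config.event_order])

    def init_state(self) -> dict:
        n = self.n
        flags = np.zeros((n, 5), dtype=np.int8)     # 0 never, 1 this_year, 2 prior
        diab_dur = np.zeros(n)
        for i, p in enumerate(self.profiles):
            if "MI" in p.cvd_history:
                flags[i, 0] = 2
            if "stroke" in p.cvd_history:
                flags[i, 1] = 2
            if "CRV" in p.cvd_history:
                flags[i, 2] = 2
            if p.cancer_history:
                flags[i, 3] = 2
            if p.diabetes_history != "none":
                flags[i, 4] = 2
                diab_dur[i] = p.years_since_diagnosis
        return {
            "age": self.age0.copy(),
            "alive": np.ones(n, dtype=bool),
            "cause": np.zeros(n, dtype=np.int8),    # 0 none, 1 vascular, 2 nonvasc
            "flags": flags,
            "diab_dur": diab_dur,
            "first_year": np.full((n, N_ENDPOINTS), -1, dtype=np.int32),
            "ly": np.zeros(n),
            "qaly": np.zeros(n),
            # horizon-truncated accumulators (one column per ci_year)
            "ly_h": np.zeros((n, len(self.config.ci_years))),
            "qaly_h": np.zeros((n, len(self.config.ci_years))),
        }

    def _indicator_matrix(self, S, rows=None):
        flags = S["flags"] if rows is None else S["flags"][rows]
        dur = S["diab_dur"] if rows is None else S["diab_dur"][rows]
        D = np.empty((flags.shape[0], len(registry.DYNAMIC_INDICATORS)))
        D[:, 0] = flags[:, 0] == 1
        D[:, 1] = flags[:, 0] == 2
        D[:, 2] = flags[:, 1] == 1
        D[:, 3] = flags[:, 1] == 2
        D[:, 4] = flags[:, 2] > 0
        D[:, 5] = flags[:, 3] > 0
        diab = flags[:, 4] > 0
        D[:, 6] = diab & (dur < 10)
        D[:, 7] = diab & (dur >= 10)
        return D

    def _dyn_lp_rows(self, S, rows):
        D = self._indicator_matrix(S, rows)
        out = np.einsum("ped,pd->pe", self.T[rows], D)
        nondiab = S["flags"][rows, 4] == 0
        out += self.hcoef[rows] * (self.hba1c_c[rows] * nondiab)[:, None]
        return out

    def _utility(self, S):
        D = self._indicator_matrix(S)
        u = (self.q_static
             + self.q_age * (S["age"] - self.age_centre)
             + D @ self.q_dyn
             + self.q_hba1c * self.hba1c_c * (S["flags"][:, 4] == 0))
        return np.clip(u, self.q_bounds[0], self.q_bounds[1])

    def step(self, S, rng, cycle: int) -> bool:
        """Advance every active person one cycle. Returns False when no one
        was active (run complete)."""
        n = self.n
        u_order = rng.random((n, N_ENDPOINTS))
        u_trig = rng.random((n, N_ENDPOINTS))
        active0 = S["alive"] & (S["age"] < AGE_CAP)
        if not active0.any():
            return False
        if self.fixed_order is None:
            order = np.argsort(u_order, axis=1)
        else:
            order = np.broadcast_to(self.fixed_order, (n, N_ENDPOINTS))
        dyn = self._dyn_lp_rows(S, slice(None))
        base = (self.b0 + self.b1 * (S["age"] - self.age_centre)[:, None]
                + self.static_lp + self.logmult)
        participate = active0.copy()
        for pos in range(N_ENDPOINTS):
            rows = np.flatnonzero(participate)
            if rows.size == 0:
                break
            e = order[rows, pos]
            nonfatal_e = e < 5
            applicable = np.ones(rows.size, dtype=bool)
            if nonfatal_e.any():
                nf = np.flatnonzero(nonfatal_e)
                applicable[nf] = S["flags"][rows[nf], e[nf]] == 0
            act = rows[applicable]
            if act.size == 0:
                continue
            ea = e[applicable]
            p = -np.expm1(-np.exp(base[act, ea] + dyn[act, ea]))
            fire = u_trig[act, ea] < p
            fr = act[fire]
            ef = ea[fire]
            if fr.size == 0:
                continue
            S["first_year"][fr, ef] = cycle
            nonfatal = ef < 5
            nf_rows = fr[nonfatal]
            if nf_rows.size:
                nf_e = ef[nonfatal]
                S["flags"][nf_rows, nf_e] = 1
                newdiab = nf_rows[nf_e == 4]
                S["diab_dur"][newdiab] = 0.0
                if self.config.within_cycle_updates:
                    dyn[nf_rows] = self._dyn_lp_rows(S, nf_rows)
            f_rows = fr[~nonfatal]
            if f_rows.size:
                f_e = ef[~nonfatal]
                S["alive"][f_rows] = False
                S["cause"][f_rows] = np.where(f_e == 5, 1, 2)
                participate[f_rows] = False
        # accounting over everyone active at cycle start
        u = self._utility(S)
        disc = _cycle_discount(self.config, cycle)
        survived = active0 & S["alive"]
        died = active0 & ~S["alive"]
        dt = np.zeros(n)
        dt[survived] = disc
        if self.config.half_cycle_correction:
            dt[died] = 0.5 * disc
        S["ly"] += dt
        S["qaly"] += u * dt
        for k, y in enumerate(self.config.ci_years):
            if cycle < y:
                S["ly_h"][:, k] += dt
                S["qaly_h"][:, k] += u * dt
        # roll cycle for survivors
        sv = survived
        S["age"][sv] += 1.0
        f = S["flags"]
        this_year = sv[:, None] & (f == 1)
        f[this_year] = 2
        S["diab_dur"][sv & (f[:, 4] > 0)] += 1.0
        return True

    def run_replicate(self, rng, S=None) -> dict:
        S = S if S is not None else self.init_state()
        cycle = 0
        horizon = self.config.horizon_years
        max_cycles = int(math.ceil(AGE_CAP - self.age0.min())) + 1
        while horizon is None or cycle < horizon:
            if cycle > max_cycles:
                break
            if not self.step(S, rng, cycle):
                break
            cycle += 1
        return S


@dataclass
class SimulationSummary:
    """Replicate-averaged per-person outcomes plus cohort aggregates."""
    per_person: pd.DataFrame
    n_replicates: int
    config: SimulationConfig
    ci_years: tuple

    def aggregate(self) -> dict:
        df = self.per_person
        out = {"n_persons": len(df),
               "mean_life_years": float(df["life_years"].mean()),
               "mean_qalys": float(df["qalys"].mean()),
               "death_vascular": float(df["death_vascular"].mean()),
               "death_nonvascular": float(df["death_nonvascular"].mean()),
               "censored_alive": float(df["censored_alive"].mean())}
        for e in ENDPOINTS:
            out[f"ci_{e}_life"] = float(df[f"ci_{e}_life"].mean())
        return out

    def summary(self) -> str:
        agg = self.aggregate()
        lines = [
            "CVD microsimulation summary",
            "===========================",
            f"persons: {agg['n_persons']}   replicates/person: {self.n_replicates}",
            f"mean remaining life years: {agg['mean_life_years']:.2f}",
            f"mean QALYs:                {agg['mean_qalys']:.2f}",
            f"deaths: vascular {agg['death_vascular']:.1%}, "
            f"nonvascular {agg['death_nonvascular']:.1%}, "
            f"censored alive {agg['censored_alive']:.1%}",
            "lifetime cumulative incidence:",
        ]
        for e in ENDPOINTS:
            lines.append(f"  {e:18s} {agg[f'ci_{e}_life']:.3f}")
        return "\n".join(lines)


def _replicate_rng(master_seed: int, replicate: int, stream: int = 0):
    ss = np.random.SeedSequence(master_seed, spawn_key=(stream, replicate))
    return np.random.Generator(np.random.PCG64(ss))


def run_microsimulation(cohort, coefficients: CoefficientSet,
                        config: SimulationConfig,
                        multiplier_fn=None) -> SimulationSummary:
    """Simulate a cohort: `replicates_per_person` lifetimes per person,
    averaged into per-person outcomes.

    `multiplier_fn(replicate) -> (n, 7) log hazard multipliers` hooks in
    treatment scenarios; None means no hazard modification.
    """
    cohort = list(cohort)
    n = len(cohort)
    if n == 0:
        raise ConfigError("cohort must be nonempty")
    reps = config.replicates_per_person
    ci_years = tuple(config.ci_years)
    engine = _VectorEngine(cohort, coefficients, config)
    acc_ly = np.zeros(n)
    acc_qaly = np.zeros(n)
    acc_ly_h = np.zeros((n, len(ci_years)))
    acc_qaly_h = np.zeros((n, len(ci_years)))
    acc_cause = np.zeros((n, 3))
    acc_ci = np.zeros((n, N_ENDPOINTS, len(ci_years) + 1))
    acc_mve = np.zeros((n, len(ci_years) + 1))
    for rep in range(reps):
        if multiplier_fn is not None:
            mult = multiplier_fn(rep)
            engine.logmult = (np.zeros((n, N_ENDPOINTS)) if mult is None
                              else np.asarray(mult, dtype=float))
        rng = _replicate_rng(config.master_seed, rep)
        S = engine.run_replicate(rng)
        acc_ly += S["ly"]
        acc_qaly += S["qaly"]
        acc_ly_h += S["ly_h"]
        acc_qaly_h += S["qaly_h"]
        acc_cause[np.arange(n), S["cause"]] += 1
        fy = S["first_year"].astype(float)
        fired = fy >= 0
        for k, y in enumerate(ci_years):
            acc_ci[:, :, k] += fired & (fy < y)
        acc_ci[:, :, -1] += fired
        mve_first = np.where(fired[:, _MVE_IDX], fy[:, _MVE_IDX], np.inf).min(axis=1)
        for k, y in enumerate(ci_years):
            acc_mve[:, k] += mve_first < y
        acc_mve[:, -1] += np.isfinite(mve_first)
    data = {
        "person_id": [p.person_id for p in cohort],
        "sex": [p.sex for p in cohort],
        "age_entry": [p.age_entry for p in cohort],
        "age_band": [registry.age_band(p.age_entry) for p in cohort],
        "townsend_quintile": [p.townsend_quintile for p in cohort],
        "cvd_history": [p.has_cvd_history for p in cohort],
        "life_years": acc_ly / reps,
        "qalys": acc_qaly / reps,
        **{f"life_years_{y}y": acc_ly_h[:, k] / reps
           for k, y in enumerate(ci_years)},
        **{f"qalys_{y}y": acc_qaly_h[:, k] / reps
           for k, y in enumerate(ci_years)},
        "censored_alive": acc_cause[:, 0] / reps,
        "death_vascular": acc_cause[:, 1] / reps,
        "death_nonvascular": acc_cause[:, 2] / reps,
    }
    for j, e in enumerate(ENDPOINTS):
        for k, y in enumerate(ci_years):
            data[f"ci_{e}_{y}y"] = acc_ci[:, j, k] / reps
        data[f"ci_{e}_life"] = acc_ci[:, j, -1] / reps
    for k, y in enumerate(ci_years):
        data[f"mve_{y}y"] = acc_mve[:, k] / reps
    data["mve_life"] = acc_mve[:, -1] / reps
    per_person = pd.DataFrame(data)
    return SimulationSummary(per_person=per_person, n_replicates=reps,
                             config=config, ci_years=ci_years)


@dataclass
class PSAResult:
    """Probabilistic sensitivity analysis over a bootstrap ensemble."""
    point: Optional[dict]           # aggregate from the replicate-0 set
    samples: pd.DataFrame           # one row of aggregates per bootstrap set
    intervals: pd.DataFrame         # metric, lo (2.5%), hi (97.5%)


def run_psa(cohort, ensemble, config: SimulationConfig) -> PSAResult:
    """Rerun the cohort summary once per coefficient set in the ensemble.

    The set with replicate_id 0 (if present) is the point estimate and is
    excluded from the percentile intervals.
    """
    ensemble = list(ensemble)
    if not ensemble:
        raise ConfigError("PSA ensemble must be nonempty")
    point = None
    rows = []
    for cs in ensemble:
        agg = run_microsimulation(cohort, cs, config).aggregate()
        agg["replicate_id"] = cs.replicate_id
        if cs.replicate_id == 0:
            point = agg
        else:
            rows.append(agg)
    if not rows:
        rows = [a for a in [point] if a is not None]
    samples = pd.DataFrame(rows)
    if len(samples) < 2:
        warnings.warn("PSA ensemble has < 2 bootstrap sets; "
                      "intervals are degenerate", stacklevel=2)
    metrics = [c for c in samples.columns if c != "replicate_id"]
    intervals = pd.DataFrame({
        "metric": metrics,
        "lo": [float(np.percentile(samples[m], 2.5)) for m in metrics],
        "hi": [float(np.percentile(samples[m], 97.5)) for m in metrics],
    })
    return PSAResult(point=point, samples=samples, intervals=intervals)
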
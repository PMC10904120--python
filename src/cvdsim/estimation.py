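"""Risk-equation estimation, bootstrap ensembles, calibration, validation.

Fitting: the Gompertz proportional-hazards equations are estimated by
maximum likelihood on annually split person-year episodes (piecewise
constant hazard within each year, log hazard linear in mid-episode age).
With a log-exposure offset this likelihood is exactly Poisson, maximised
here by Newton/IRLS. Time-updated event-history covariates enter through
the episode split, mirroring the simulator's annual-cycle discretization.

Observed cumulative incidence treats death from other causes as a
competing risk (Aalen-Johansen), with a 1-KM variant available; both are
delegated to lifelines.

Calibration fits additive shifts on the log baseline hazard by minimising
the squared distance between predicted and observed cumulative incidence
curves. The predicted curve is deterministic: model hazards are evaluated
on the target data's observed risk sets and event histories and combined
with the observed all-cause survival, so the search objective carries no
Monte Carlo noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from . import registry, risk
from .coefficients import (Baseline, Calibration, CoefficientSet,
                           RiskEquation)
from .errors import CalibrationError, EstimationError
from .registry import ENDPOINTS


@dataclass
class FollowUpRecords:
    """Individual-participant follow-up: first-event times and censoring.

    events: long DataFrame (person_id, endpoint, time) of first
    occurrences, deaths included; censor_time: per-person administrative
    censoring horizon (years from entry).
    """

    profiles: list
    events: pd.DataFrame
    censor_time: dict
    max_years: float

    def __post_init__(self):
        if len(self.events) and not {"person_id", "endpoint", "time"}.issubset(
                self.events.columns):
            raise EstimationError(
                "events frame needs columns person_id, endpoint, time")

    def subset(self, person_ids) -> "FollowUpRecords":
        wanted = set(person_ids)
        profiles = [p for p in self.profiles if p.person_id in wanted]
        ev = self.events[self.events.person_id.isin(wanted)].reset_index(drop=True)
        ct = {pid: t for pid, t in self.censor_time.items() if pid in wanted}
        return FollowUpRecords(profiles, ev, ct, self.max_years)

    def death_time(self) -> dict:
        """person_id -> (time, cause) for deaths, absent if censored alive."""
        out = {}
        dead = self.events[self.events.endpoint.isin(
            ("vascular_death", "nonvascular_death"))]
        for r in dead.itertuples():
            out[r.person_id] = (r.time, r.endpoint)
        return out


def write_followup(ipd: FollowUpRecords, path):
    """Long-format IPD CSV: person_id, endpoint, time, indicator."""
    rows = [{"person_id": r.person_id, "endpoint": r.endpoint,
             "time": r.time, "indicator": 1}
            for r in ipd.events.itertuples()]
    rows += [{"person_id": pid, "endpoint": "censor", "time": t, "indicator": 0}
             for pid, t in ipd.censor_time.items()]
    pd.DataFrame(rows, columns=["person_id", "endpoint", "time",
                                "indicator"]).to_csv(path, index=False)


def read_followup(path, profiles) -> FollowUpRecords:
    df = pd.read_csv(path, dtype={"person_id": str})
    ev = df[df.indicator == 1][["person_id", "endpoint", "time"]]
    cens = df[df.indicator == 0]
    censor_time = dict(zip(cens.person_id, cens.time))
    max_years = float(df.time.max()) if len(df) else 0.0
    return FollowUpRecords(list(profiles), ev.reset_index(drop=True),
                           censor_time, max_years)


# ---------------------------------------------------------------------------
# episode construction


def _person_history(events: list):
    """events: [(endpoint, time)] sorted; returns lookup for dynamic
    covariates at a given year index."""
    return sorted(events, key=lambda et: et[1])


def build_episodes(ipd: FollowUpRecords, endpoint: str,
                   covariates: Sequence[str],
                   population: str = "pooled",
                   centring: dict = None) -> pd.DataFrame:
    """Annual person-year episodes for one endpoint.

    Columns: exposure, event, age (mid-episode), one column per requested
    covariate. People already having the endpoint at entry are excluded
    (first occurrences only); follow-up for the endpoint ends at the first
    of the endpoint event, death, or censoring.
    """
    c = centring if centring is not None else registry.CENTRING_DEFAULTS
    ev_by_person = {}
    for r in ipd.events.itertuples():
        ev_by_person.setdefault(r.person_id, []).append((r.endpoint, r.time))
    death = ipd.death_time()
    rows = []
    for p in ipd.profiles:
        if population == "no_cvd" and p.has_cvd_history:
            continue
        if population == "cvd" and not p.has_cvd_history:
            continue
        from .profiles import initial_state
        state0 = initial_state(p)
        if endpoint in registry.EVENT_ENDPOINTS \
                and state0.event_flags[endpoint] != "never":
            continue
        events = _person_history(ev_by_person.get(p.person_id, []))
        t_end = ipd.censor_time.get(p.person_id, ipd.max_years)
        t_event = None
        for e, t in events:
            if e == endpoint:
                t_event = t
                break
        if p.person_id in death:
            t_end = min(t_end, death[p.person_id][0])
        if t_event is not None:
            t_end = min(t_end, t_event)
        n_years = int(math.ceil(t_end)) if t_end > 0 else 0
        for y in range(n_years):
            exposure = min(t_end, y + 1) - y
            if exposure <= 0:
                continue
            is_event = t_event is not None and y <= t_event < y + 1 \
                and abs(t_end - t_event) < 1e-12
            state = _state_at_year(p, events, y, endpoint)
            row = {"person_id": p.person_id,
                   "exposure": exposure,
                   "event": 1 if is_event else 0,
                   "age": p.age_entry + y + exposure / 2.0}
            for name in covariates:
                row[name] = registry.resolve_covariate(name, p, state, c)
            rows.append(row)
    return pd.DataFrame(rows)


def _state_at_year(profile, events, year, skip_endpoint):
    """Reconstruct the dynamic state in force during calendar year
    [year, year+1) from the observed event times."""
    from .profiles import initial_state
    state = initial_state(profile)
    state.current_age = profile.age_entry + year
    for e, t in events:
        if e == skip_endpoint or e in ("vascular_death", "nonvascular_death"):
            continue
        if e not in registry.EVENT_ENDPOINTS:
            continue
        if state.event_flags[e] != "never":
            continue
        if t < year:
            state.event_flags[e] = "prior_years"
            years_since = int(year - math.floor(t))
            state.years_since[e] = years_since
            if e == "diabetes":
                state.diabetes_duration = float(years_since)
        elif t < year + 1:
            state.event_flags[e] = "this_year"
            state.years_since[e] = 0
            if e == "diabetes":
                state.diabetes_duration = 0.0
    return state


# ---------------------------------------------------------------------------
# Poisson IRLS (piecewise-annual Gompertz PH maximum likelihood)


def _poisson_irls(X, y, offset, weights=None, max_iter=50, tol=1e-9):
    """Newton-Raphson for Poisson regression with log link and offset.

    `weights` are frequency weights (person multiplicities under
    bootstrap resampling). Returns (beta, cov, loglik, n_iter); raises
    EstimationError on non-convergence with the iteration trace in the
    message.
    """
    n, k = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    beta = np.zeros(k)
    # start intercept at the crude log rate
    rate = (w * y).sum() / (w * np.exp(offset)).sum()
    beta[0] = math.log(max(rate, 1e-12))
    trace = []
    for it in range(max_iter):
        eta = X @ beta + offset
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        score = X.T @ (w * (y - mu))
        info = (X * (w * mu)[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise EstimationError(
                "singular information matrix (collinear covariates?)") from None
        change = float(np.max(np.abs(step)))
        trace.append(change)
        beta = beta + step
        if change < tol:
            eta = np.clip(X @ beta + offset, -30, 30)
            mu = np.exp(eta)
            ll = float(np.sum(w * (y * eta - mu)))  # up to the log y! term
            info = (X * (w * mu)[:, None]).T @ X
            cov = np.linalg.inv(info)
            return beta, cov, ll, it + 1
    raise EstimationError(
        f"IRLS failed to converge in {max_iter} iterations; "
        f"step-size trace: {['%.3g' % t for t in trace[-5:]]}")


class GompertzPHResults:
    """Fitted risk equation with standard errors and diagnostics."""

    def __init__(self, equation: RiskEquation, bse: dict, loglik: float,
                 n_events: int, n_episodes: int, dropped: list, n_iter: int):
        self.equation = equation
        self.bse = bse                  # includes 'intercept' and 'age_slope'
        self.loglik = loglik
        self.n_events = n_events
        self.n_episodes = n_episodes
        self.dropped = dropped          # constant covariates removed from fit
        self.n_iter = n_iter

    @property
    def params(self) -> dict:
        eq = self.equation
        out = {"intercept": eq.baseline.log_hazard_intercept,
               "age_slope": eq.baseline.age_slope}
        out.update(eq.coefficients)
        return out

    def summary(self) -> str:
        lines = [f"Gompertz PH fit: {self.equation.endpoint} "
                 f"({self.equation.population})",
                 f"events {self.n_events}, person-year episodes "
                 f"{self.n_episodes}, log-likelihood {self.loglik:.2f}",
                 f"{'term':24s}{'coef':>10s}{'se':>10s}"]
        for name, value in self.params.items():
            se = self.bse.get(name, float("nan"))
            lines.append(f"{name:24s}{value:10.4f}{se:10.4f}")
        if self.dropped:
            lines.append(f"dropped constant covariates: {self.dropped}")
        return "\n".join(lines)


def fit_risk_equation(ipd: FollowUpRecords, endpoint: str, population: str,
                      covariates: Sequence[str],
                      centring: dict = None) -> GompertzPHResults:
    """ML Gompertz PH fit for one endpoint on annual episodes.

    Constant (non-identifiable) covariates are dropped and reported in
    the result, never silently zeroed.
    """
    c = centring if centring is not None else dict(registry.CENTRING_DEFAULTS)
    episodes = build_episodes(ipd, endpoint, covariates, population, c)
    if len(episodes) == 0:
        raise EstimationError(
            f"no person-time at risk for {endpoint}/{population}")
    n_events = int(episodes["event"].sum())
    if n_events == 0:
        raise EstimationError(
            f"no {endpoint} events in the {population} subset")
    kept, dropped = [], []
    for name in covariates:
        if episodes[name].nunique() > 1:
            kept.append(name)
        else:
            dropped.append(name)
    if dropped:
        warnings.warn(f"constant covariates dropped from "
                      f"{endpoint}/{population} fit: {dropped}", stacklevel=2)
    X = np.column_stack(
        [np.ones(len(episodes)),
         episodes["age"].to_numpy() - c["age"]]
        + [episodes[name].to_numpy(dtype=float) for name in kept])
    y = episodes["event"].to_numpy(dtype=float)
    offset = np.log(episodes["exposure"].to_numpy(dtype=float))
    beta, cov, ll, n_iter = _poisson_irls(X, y, offset)
    se = np.sqrt(np.diag(cov))
    names = ["intercept", "age_slope"] + kept
    eq = RiskEquation(endpoint=endpoint, population=population,
                      baseline=Baseline(log_hazard_intercept=float(beta[0]),
                                        age_slope=float(beta[1])),
                      coefficients={n: float(b)
                                    for n, b in zip(kept, beta[2:])})
    return GompertzPHResults(equation=eq,
                             bse=dict(zip(names, se.astype(float))),
                             loglik=ll, n_events=n_events,
                             n_episodes=len(episodes), dropped=dropped,
                             n_iter=n_iter)


@dataclass(frozen=True)
class FitSpec:
    """One equation to (re)fit: endpoint, population, covariate list."""
    endpoint: str
    population: str
    covariates: tuple


def bootstrap_ensemble(ipd: FollowUpRecords, fit_specs: Sequence[FitSpec],
                       B: int, seed: int,
                       base_set: CoefficientSet) -> list:
    """B person-level bootstrap refits -> CoefficientSets (replicate 1..B).

    Resampling persons with replacement is implemented as
    frequency-weighted refits on the episode tables (a person drawn k
    times contributes their episodes with weight k), which is the same
    estimator without rebuilding episodes per replicate. Equations not
    named in `fit_specs` (and the QoL model) are carried over from
    `base_set`. Failed refits are skipped with a warning; deterministic
    given the seed.
    """
    if B < 1:
        raise EstimationError("B must be >= 1")
    rng = np.random.default_rng(seed)
    c = base_set.centring
    # precompute design per fit spec
    designs = []
    for spec in fit_specs:
        episodes = build_episodes(ipd, spec.endpoint, list(spec.covariates),
                                  spec.population, c)
        if len(episodes) == 0 or episodes["event"].sum() == 0:
            raise EstimationError(
                f"no events for {spec.endpoint}/{spec.population}")
        kept = [nm for nm in spec.covariates if episodes[nm].nunique() > 1]
        dropped = [nm for nm in spec.covariates if nm not in kept]
        if dropped:
            warnings.warn(f"constant covariates dropped from "
                          f"{spec.endpoint}/{spec.population} bootstrap: "
                          f"{dropped}", stacklevel=2)
        X = np.column_stack(
            [np.ones(len(episodes)),
             episodes["age"].to_numpy() - c["age"]]
            + [episodes[nm].to_numpy(dtype=float) for nm in kept])
        y = episodes["event"].to_numpy(dtype=float)
        offset = np.log(episodes["exposure"].to_numpy(dtype=float))
        # map episode rows to cohort-wide person indices so one cohort
        # resample per replicate drives every equation jointly
        id_index = {p.person_id: i for i, p in enumerate(ipd.profiles)}
        person_idx = episodes["person_id"].map(id_index).to_numpy()
        designs.append((spec, kept, X, y, offset, person_idx))
    n_cohort = len(ipd.profiles)
    out = []
    n_failed = 0
    for b in range(1, B + 1):
        counts = rng.multinomial(n_cohort, np.full(n_cohort, 1.0 / n_cohort))
        cs = base_set.copy(replicate_id=b)
        try:
            for spec, kept, X, y, offset, person_idx in designs:
                w = counts[person_idx].astype(float)
                beta, _, _, _ = _poisson_irls(X, y, offset, weights=w)
                eq = RiskEquation(
                    endpoint=spec.endpoint, population=spec.population,
                    baseline=Baseline(log_hazard_intercept=float(beta[0]),
                                      age_slope=float(beta[1])),
                    coefficients={nm: float(v)
                                  for nm, v in zip(kept, beta[2:])})
                cs.equations[(spec.endpoint, spec.population)] = eq
            cs.validate()
            out.append(cs)
        except EstimationError as exc:
            n_failed += 1
            warnings.warn(f"bootstrap replicate {b} skipped: {exc}",
                          stacklevel=2)
    if n_failed:
        warnings.warn(f"{n_failed}/{B} bootstrap replicates failed",
                      stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# observed incidence, calibration, validation


def _first_event_table(ipd: FollowUpRecords, endpoint: str) -> pd.DataFrame:
    """Per person: duration and status (0 censored, 1 endpoint,
    2 competing death)."""
    death = ipd.death_time()
    ev = ipd.events[ipd.events.endpoint == endpoint]
    t_event = dict(zip(ev.person_id, ev.time))
    rows = []
    for p in ipd.profiles:
        from .profiles import initial_state
        if endpoint in registry.EVENT_ENDPOINTS \
                and initial_state(p).event_flags[endpoint] != "never":
            continue
        t_cens = ipd.censor_time.get(p.person_id, ipd.max_years)
        te = t_event.get(p.person_id)
        td = death.get(p.person_id)
        candidates = [(t_cens, 0)]
        if te is not None:
            candidates.append((te, 1))
        if td is not None and td[1] != endpoint:
            candidates.append((td[0], 2))
        t, status = min(candidates, key=lambda ts: (ts[0], -ts[1]))
        rows.append({"person_id": p.person_id, "time": t, "status": status})
    return pd.DataFrame(rows)


def _step_interp(x, xp, fp, left):
    """Right-continuous step-function lookup (KM/AJ curves are steps,
    linear interpolation would bias between event times)."""
    x = np.asarray(x, dtype=float)
    xp = np.asarray(xp, dtype=float)
    fp = np.asarray(fp, dtype=float)
    idx = np.searchsorted(xp, x, side="right") - 1
    out = np.where(idx >= 0, fp[np.clip(idx, 0, len(fp) - 1)], left)
    return out


def observed_cumulative_incidence(ipd: FollowUpRecords, endpoint: str,
                                  horizon: int,
                                  competing_risks: bool = True) -> pd.Series:
    """Observed cumulative incidence of an endpoint at years 1..horizon.

    Default is the Aalen-Johansen estimator with death from other causes
    as a competing risk; `competing_risks=False` gives 1 - Kaplan-Meier
    with competing deaths censored.
    """
    tbl = _first_event_table(ipd, endpoint)
    years = np.arange(1, horizon + 1)
    if len(tbl) == 0 or (tbl.status == 1).sum() == 0:
        return pd.Series(np.zeros(len(years)), index=years, name=endpoint)
    if competing_risks and (tbl.status == 2).any():
        from lifelines import AalenJohansenFitter
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ajf = AalenJohansenFitter(calculate_variance=False)
            ajf.fit(tbl.time, tbl.status, event_of_interest=1)
        curve = ajf.cumulative_density_
        vals = _step_interp(years, curve.index.to_numpy(),
                            curve.iloc[:, 0].to_numpy(), left=0.0)
    else:
        from lifelines import KaplanMeierFitter
        kmf = KaplanMeierFitter()
        kmf.fit(tbl.time, tbl.status == 1)
        sf = kmf.survival_function_
        vals = 1.0 - _step_interp(years, sf.index.to_numpy(),
                                  sf.iloc[:, 0].to_numpy(), left=1.0)
    return pd.Series(vals, index=years, name=endpoint)


def _expected_annual_hazard(cs: CoefficientSet, ipd: FollowUpRecords,
                            endpoint: str, population: str,
                            horizon: int):
    """Per follow-up year: exposure-weighted mean model hazard among
    those observed at risk, and the observed at-risk fraction (exposure /
    cohort size). Uses the target data's observed histories, so predicted
    and observed incidence share exactly the same risk sets."""
    episodes = build_episodes(ipd, endpoint, [], population, cs.centring)
    c = cs.centring
    ev_by_person = {}
    for r in ipd.events.itertuples():
        ev_by_person.setdefault(r.person_id, []).append((r.endpoint, r.time))
    num = np.zeros(horizon)
    den = np.zeros(horizon)
    by_id = {p.person_id: p for p in ipd.profiles}
    n_at_entry = 0
    seen = set()
    for r in episodes.itertuples():
        p = by_id[r.person_id]
        if r.person_id not in seen:
            seen.add(r.person_id)
            n_at_entry += 1
        y = int(r.age - p.age_entry)
        if y >= horizon:
            continue
        eq = cs.equation(endpoint, p.population)
        state = _state_at_year(p, _person_history(
            ev_by_person.get(p.person_id, [])), y, endpoint)
        h = risk.annual_hazard(p, state, eq, c)
        num[y] += h * r.exposure
        den[y] += r.exposure
    with np.errstate(invalid="ignore"):
        hbar = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    at_risk_frac = den / max(n_at_entry, 1)
    return hbar, at_risk_frac


@dataclass
class CalibrationReport:
    endpoint: str
    population: str
    intercept_shift: float
    slope_shift: float
    objective_pre: float
    objective_post: float


def calibrate(cs: CoefficientSet, target_ipd: FollowUpRecords,
              horizon: int = None, fit_slope: bool = False,
              populations: Sequence[str] = ("no_cvd", "cvd"),
              endpoints: Sequence[str] = None,
              tol: float = 1e-6, max_iter: int = 200):
    """Set per-equation calibration shifts against a target cohort.

    For each endpoint/population, the intercept shift (optionally also an
    age-slope shift) minimises the sum over follow-up years of squared
    differences between the model-predicted and observed cumulative
    incidence. Returns (calibrated copy of the set, list of
    CalibrationReport); never worsens the objective.
    """
    horizon = horizon or int(math.ceil(target_ipd.max_years))
    endpoints = list(endpoints) if endpoints is not None else list(ENDPOINTS)
    out = cs.copy()
    for eq in out.equations.values():   # shifts are re-estimated from scratch
        eq.calibration = Calibration()
    reports = []
    for endpoint in endpoints:
        pops = ["pooled"] if (endpoint, "pooled") in cs.equations \
            else list(populations)
        for population in pops:
            sub = target_ipd if population == "pooled" else FollowUpRecords(
                [p for p in target_ipd.profiles
                 if p.population == population],
                target_ipd.events, target_ipd.censor_time,
                target_ipd.max_years)
            if not sub.profiles:
                continue
            obs = observed_cumulative_incidence(sub, endpoint, horizon)
            hbar, at_risk = _expected_annual_hazard(out, sub, endpoint,
                                                    population, horizon)

            def objective(shift, slope=0.0):
                years = np.arange(horizon, dtype=float)
                mult = np.exp(shift + slope * years)  # slope on follow-up year
                p_year = -np.expm1(-hbar * mult)
                pred = np.cumsum(at_risk * p_year)
                return float(np.sum((pred - obs.to_numpy()) ** 2))

            pre = objective(0.0)
            if fit_slope:
                res = minimize(lambda v: objective(v[0], v[1]),
                               x0=np.zeros(2), method="Nelder-Mead",
                               options={"xatol": tol, "fatol": tol ** 2,
                                        "maxiter": max_iter})
                if not res.success and res.fun > pre:
                    raise CalibrationError(
                        f"calibration failed for {endpoint}/{population}",
                        best_shifts=tuple(res.x))
                shift, slope = (res.x if res.fun <= pre else (0.0, 0.0))
            else:
                res = minimize_scalar(objective, bounds=(-4.0, 4.0),
                                      method="bounded",
                                      options={"xatol": tol,
                                               "maxiter": max_iter})
                shift = float(res.x) if res.fun <= pre else 0.0
                slope = 0.0
            post = objective(shift, slope)
            eq = out.equation(endpoint, population)
            eq.calibration = Calibration(intercept_shift=float(shift),
                                         slope_shift=float(slope))
            reports.append(CalibrationReport(
                endpoint=endpoint, population=population,
                intercept_shift=float(shift), slope_shift=float(slope),
                objective_pre=pre, objective_post=post))
    return out, reports


@dataclass
class ValidationReport:
    """Predicted vs observed cumulative incidence per endpoint/subgroup."""
    table: pd.DataFrame        # subgroup, endpoint, year, observed, predicted,
    #                            ratio, difference, n, n_events
    skipped: list = field(default_factory=list)

    def to_json(self) -> dict:
        return {"skipped": self.skipped,
                "rows": self.table.to_dict("records")}


def validate(cs: CoefficientSet, observed_ipd: FollowUpRecords,
             subgroups: dict = None, horizons: dict = None,
             default_horizon: int = None, replicates: int = 10,
             seed: int = 0) -> ValidationReport:
    """Compare engine-simulated with observed cumulative incidence.

    `subgroups` maps name -> predicate(profile); None means the whole
    cohort. `horizons` gives per-endpoint follow-up limits (e.g. shorter
    incident-diabetes follow-up); others use `default_horizon` (defaults
    to the data's follow-up ceiling). Empty subgroups are skipped and
    reported.
    """
    from .engine import SimulationConfig, run_microsimulation

    default_horizon = default_horizon or int(math.ceil(observed_ipd.max_years))
    horizons = horizons or {}
    subgroups = subgroups or {"all": lambda p: True}
    rows = []
    skipped = []
    for name, predicate in subgroups.items():
        profiles = [p for p in observed_ipd.profiles if predicate(p)]
        if not profiles:
            skipped.append(name)
            continue
        sub = observed_ipd.subset([p.person_id for p in profiles])
        max_h = max([default_horizon] + list(horizons.values()))
        config = SimulationConfig(replicates_per_person=replicates,
                                  horizon_years=max_h, master_seed=seed,
                                  ci_years=tuple(range(1, max_h + 1)))
        summary = run_microsimulation(profiles, cs, config)
        for endpoint in ENDPOINTS:
            h = int(horizons.get(endpoint, default_horizon))
            obs = observed_cumulative_incidence(sub, endpoint, h)
            tbl = _first_event_table(sub, endpoint)
            for year in range(1, h + 1):
                pred = float(summary.per_person[f"ci_{endpoint}_{year}y"].mean())
                o = float(obs.loc[year])
                n_events = int(((tbl.status == 1) & (tbl.time < year)).sum())
                rows.append({"subgroup": name, "endpoint": endpoint,
                             "year": year, "observed": o, "predicted": pred,
                             "ratio": pred / o if o > 0 else float("nan"),
                             "difference": pred - o,
                             "n": len(profiles), "n_events": n_events})
    return ValidationReport(table=pd.DataFrame(rows), skipped=skipped)
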
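"""Individual risk profiles, dynamic simulation state, and cohort file IO.

Cohorts are UTF-8 CSV, header row, one person per row. Validation is total:
a malformed row raises a typed error and no profile is constructed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import registry
from .errors import CohortRowError, CohortSchemaError

MANDATORY_COLUMNS = [
    "person_id", "age_entry", "sex", "ethnicity", "smoking", "bmi_category",
    "ldl", "hdl", "hba1c", "creatinine", "sbp", "dbp",
    "treated_hypertension", "diabetes_history", "years_since_diagnosis",
    "cancer_history", "cvd_history", "severe_mental_illness",
    "physical_activity", "diet_unhealthy", "townsend_quintile",
    "statin_at_entry",
]
OPTIONAL_COLUMNS = ["egfr", "albuminuria", "ten_year_cvd_risk"]

_POSITIVE_FIELDS = ("ldl", "hdl", "hba1c", "creatinine", "sbp", "dbp")


@dataclass(frozen=True)
class IndividualProfile:
    """Fixed baseline characteristics of one simulated person."""

    person_id: str
    age_entry: float
    sex: str
    ethnicity: str
    smoking: str
    bmi_category: str
    ldl: float                      # mmol/L
    hdl: float                      # mmol/L
    hba1c: float                    # mmol/mol
    creatinine: float               # umol/L
    sbp: float                      # mmHg
    dbp: float                      # mmHg
    treated_hypertension: bool
    diabetes_history: str           # none / type1 / type2
    years_since_diagnosis: float    # 0 when no diabetes
    cancer_history: bool
    cvd_history: frozenset          # subset of {MI, stroke, CRV, PAD, other_CHD}
    severe_mental_illness: bool
    physical_activity: str
    diet_unhealthy: bool
    townsend_quintile: int          # 1 = least deprived
    statin_at_entry: bool
    egfr: Optional[float] = None            # mL/min/1.73m2, derivable
    albuminuria: Optional[bool] = None
    ten_year_cvd_risk: Optional[float] = None  # percent, external score

    def __post_init__(self):
        if not self.person_id:
            raise ValueError("person_id must be nonempty")
        if not 0 < self.age_entry <= registry.AGE_CAP:
            raise ValueError(f"age_entry {self.age_entry} out of (0, {registry.AGE_CAP}]")
        _check_level("sex", self.sex, registry.SEXES)
        _check_level("ethnicity", self.ethnicity, registry.ETHNICITIES)
        _check_level("smoking", self.smoking, registry.SMOKING_LEVELS)
        _check_level("bmi_category", self.bmi_category, registry.BMI_CATEGORIES)
        _check_level("diabetes_history", self.diabetes_history, registry.DIABETES_TYPES)
        _check_level("physical_activity", self.physical_activity,
                     registry.PHYSICAL_ACTIVITY_LEVELS)
        for name in _POSITIVE_FIELDS:
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        if self.townsend_quintile not in (1, 2, 3, 4, 5):
            raise ValueError(
                f"townsend_quintile must be in 1..5, got {self.townsend_quintile}")
        if self.diabetes_history == "none":
            if self.years_since_diagnosis != 0:
                raise ValueError("years_since_diagnosis must be 0 without diabetes")
        elif self.years_since_diagnosis < 0:
            raise ValueError("years_since_diagnosis must be >= 0")
        bad = set(self.cvd_history) - set(registry.CVD_HISTORY_EVENTS)
        if bad:
            raise ValueError(
                f"unknown cvd_history events {sorted(bad)}; "
                f"allowed: {list(registry.CVD_HISTORY_EVENTS)}")

    @property
    def has_cvd_history(self) -> bool:
        return len(self.cvd_history) > 0

    @property
    def population(self) -> str:
        """Which risk-equation population this person is routed to."""
        return "cvd" if self.has_cvd_history else "no_cvd"

    def egfr_value(self) -> float:
        """Supplied eGFR, or the CKD-EPI 2021 creatinine estimate."""
        if self.egfr is not None:
            return self.egfr
        return egfr_ckd_epi(self.creatinine, self.age_entry, self.sex)


def _check_level(name, value, allowed):
    if value not in allowed:
        raise ValueError(f"{name}={value!r} not in allowed levels {list(allowed)}")


def egfr_ckd_epi(creatinine_umol: float, age: float, sex: str) -> float:
    """CKD-EPI 2021 race-free eGFR (mL/min/1.73m2) from serum creatinine."""
    scr = creatinine_umol / 88.4  # umol/L -> mg/dL
    if sex == "female":
        kappa, alpha, sex_mult = 0.7, -0.241, 1.012
    else:
        kappa, alpha, sex_mult = 0.9, -0.302, 1.0
    r = scr / kappa
    return 142.0 * min(r, 1.0) ** alpha * max(r, 1.0) ** -1.200 \
        * 0.9938 ** age * sex_mult


@dataclass
class DynamicState:
    """Time-updated state of one person during simulation.

    Event flags move monotonically never -> this_year -> prior_years
    (first occurrences only). `years_since` is 0 in the event year.
    """

    current_age: float
    alive: bool = True
    cause_of_death: str = "none"        # none / vascular / nonvascular
    event_flags: dict = field(default_factory=dict)
    years_since: dict = field(default_factory=dict)
    diabetes_duration: float = 0.0
    on_statin: bool = False
    ldl_current: float = 0.0

    def __post_init__(self):
        for ev in registry.EVENT_ENDPOINTS:
            self.event_flags.setdefault(ev, "never")
            self.years_since.setdefault(ev, 0)

    def roll_cycle(self):
        """End-of-cycle update for a survivor: age +1, phase flags roll over."""
        self.current_age += 1.0
        for ev in registry.EVENT_ENDPOINTS:
            if self.event_flags[ev] == "this_year":
                self.event_flags[ev] = "prior_years"
                self.years_since[ev] = 1
            elif self.event_flags[ev] == "prior_years":
                self.years_since[ev] += 1
        if self.event_flags["diabetes"] != "never":
            self.diabetes_duration += 1.0

    def record_event(self, endpoint: str):
        if self.event_flags[endpoint] != "never":
            raise ValueError(f"{endpoint} already in history (first occurrences only)")
        self.event_flags[endpoint] = "this_year"
        self.years_since[endpoint] = 0
        if endpoint == "diabetes":
            self.diabetes_duration = 0.0


def initial_state(profile: IndividualProfile) -> DynamicState:
    """Entry-time DynamicState implied by a baseline profile."""
    state = DynamicState(current_age=profile.age_entry,
                         ldl_current=profile.ldl,
                         on_statin=profile.statin_at_entry)
    for ev, key in (("mi", "MI"), ("stroke", "stroke"), ("crv", "CRV")):
        if key in profile.cvd_history:
            state.event_flags[ev] = "prior_years"
            state.years_since[ev] = 1
    if profile.cancer_history:
        state.event_flags["cancer"] = "prior_years"
        state.years_since["cancer"] = 1
    if profile.diabetes_history != "none":
        state.event_flags["diabetes"] = "prior_years"
        state.years_since["diabetes"] = max(1, int(profile.years_since_diagnosis))
        state.diabetes_duration = profile.years_since_diagnosis
    return state


_BOOL_TRUE = {"1", "true", "yes", "y"}
_BOOL_FALSE = {"0", "false", "no", "n", ""}


def _parse_bool(raw, row, name):
    s = str(raw).strip().lower()
    if s in ("nan", "none"):
        s = ""
    if s in _BOOL_TRUE:
        return True
    if s in _BOOL_FALSE:
        return False
    raise CohortRowError(row, f"{name}={raw!r} is not a boolean flag")


def _parse_float(raw, row, name, optional=False):
    s = str(raw).strip()
    if s in ("", "nan", "None"):
        if optional:
            return None
        raise CohortRowError(row, f"{name} is mandatory but missing")
    try:
        return float(s)
    except ValueError:
        raise CohortRowError(row, f"{name}={raw!r} is not numeric") from None


def read_cohort(path) -> list:
    """Read a cohort CSV into validated IndividualProfile objects.

    Row numbers (1-based data rows) are reported in errors.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - passthrough
        raise CohortSchemaError(f"cannot read cohort file {path}: {exc}") from exc
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"cohort file missing mandatory columns: {missing}")
    profiles = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        profiles.append(_profile_from_record(rec, i))
    return profiles


def _profile_from_record(rec: dict, row: int) -> IndividualProfile:
    cvd_raw = str(rec.get("cvd_history", "")).strip()
    cvd = frozenset(x for x in (s.strip() for s in cvd_raw.split(";")) if x)
    try:
        quintile = int(float(rec["townsend_quintile"]))
    except ValueError:
        raise CohortRowError(row, f"townsend_quintile={rec['townsend_quintile']!r} "
                                  "is not an integer") from None
    kwargs = dict(
        person_id=str(rec["person_id"]).strip(),
        age_entry=_parse_float(rec["age_entry"], row, "age_entry"),
        sex=str(rec["sex"]).strip(),
        ethnicity=str(rec["ethnicity"]).strip(),
        smoking=str(rec["smoking"]).strip(),
        bmi_category=str(rec["bmi_category"]).strip(),
        ldl=_parse_float(rec["ldl"], row, "ldl"),
        hdl=_parse_float(rec["hdl"], row, "hdl"),
        hba1c=_parse_float(rec["hba1c"], row, "hba1c"),
        creatinine=_parse_float(rec["creatinine"], row, "creatinine"),
        sbp=_parse_float(rec["sbp"], row, "sbp"),
        dbp=_parse_float(rec["dbp"], row, "dbp"),
        treated_hypertension=_parse_bool(rec["treated_hypertension"], row,
                                         "treated_hypertension"),
        diabetes_history=str(rec["diabetes_history"]).strip(),
        years_since_diagnosis=_parse_float(rec["years_since_diagnosis"], row,
                                           "years_since_diagnosis"),
        cancer_history=_parse_bool(rec["cancer_history"], row, "cancer_history"),
        cvd_history=cvd,
        severe_mental_illness=_parse_bool(rec["severe_mental_illness"], row,
                                          "severe_mental_illness"),
        physical_activity=str(rec["physical_activity"]).strip(),
        diet_unhealthy=_parse_bool(rec["diet_unhealthy"], row, "diet_unhealthy"),
        townsend_quintile=quintile,
        statin_at_entry=_parse_bool(rec["statin_at_entry"], row, "statin_at_entry"),
    )
    for name in OPTIONAL_COLUMNS:
        if name in rec:
            if name == "albuminuria":
                raw = str(rec[name]).strip()
                kwargs[name] = None if raw in ("", "nan", "None") \
                    else _parse_bool(raw, row, name)
            else:
                kwargs[name] = _parse_float(rec[name], row, name, optional=True)
    try:
        return IndividualProfile(**kwargs)
    except ValueError as exc:
        raise CohortRowError(row, str(exc)) from None


def cohort_to_frame(profiles) -> pd.DataFrame:
    """Cohort as a DataFrame in the canonical CSV column layout."""
    rows = []
    for p in profiles:
        d = dataclasses.asdict(p)
        d["cvd_history"] = ";".join(sorted(p.cvd_history))
        for b in ("treated_hypertension", "cancer_history", "severe_mental_illness",
                  "diet_unhealthy", "statin_at_entry"):
            d[b] = int(d[b])
        d["albuminuria"] = "" if p.albuminuria is None else int(p.albuminuria)
        for opt in ("egfr", "ten_year_cvd_risk"):
            if d[opt] is None:
                d[opt] = ""
        rows.append(d)
    return pd.DataFrame(rows, columns=MANDATORY_COLUMNS + OPTIONAL_COLUMNS)


def write_cohort(profiles, path):
    cohort_to_frame(profiles).to_csv(path, index=False)
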
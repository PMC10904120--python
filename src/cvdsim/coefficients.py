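"""Parametric risk-equation parameter sets and their JSON serialization.

A CoefficientSet bundles everything the simulator needs: one Gompertz
proportional-hazards risk equation per endpoint for each applicable
population (separate equations without/with CVD history, pooled for
incident cancer and diabetes), the EQ-5D utility regression, centring
constants, and a replicate id (0 = point estimate, k >= 1 = bootstrap
replicate for probabilistic sensitivity analysis).

The JSON schema is documented in docs/coefficient_schema.md; the `version`
field is mandatory and checked.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import pandas as pd

from . import registry
from .errors import CoefficientSetError, CovariateError

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class Baseline:
    """Gompertz baseline: log hazard = intercept + slope * (age - centre)."""
    log_hazard_intercept: float
    age_slope: float = 0.0


@dataclass
class Calibration:
    """Additive recalibration shifts on the log baseline hazard."""
    intercept_shift: float = 0.0
    slope_shift: float = 0.0


@dataclass
class RiskEquation:
    endpoint: str
    population: str
    baseline: Baseline
    coefficients: dict = field(default_factory=dict)   # name -> log HR
    calibration: Calibration = field(default_factory=Calibration)

    def __post_init__(self):
        if self.endpoint not in registry.ENDPOINTS:
            raise CoefficientSetError(f"unknown endpoint {self.endpoint!r}")
        if self.population not in registry.POPULATIONS:
            raise CoefficientSetError(f"unknown population {self.population!r}")
        known = registry.known_covariates()
        for name, value in self.coefficients.items():
            if name not in known:
                raise CovariateError(
                    f"equation {self.endpoint}/{self.population}: "
                    f"coefficient {name!r} is not in the covariate registry")
            if not isinstance(value, (int, float)) or value != value:
                raise CoefficientSetError(
                    f"equation {self.endpoint}/{self.population}: "
                    f"coefficient {name!r} is not numeric: {value!r}")


@dataclass
class QoLModel:
    """Linear EQ-5D utility model; predictions clamp to [-0.594, 1]."""
    intercept: float
    coefficients: dict = field(default_factory=dict)
    bounds: tuple = (registry.EQ5D_FLOOR, registry.EQ5D_CEILING)

    def __post_init__(self):
        known = registry.known_covariates()
        for name in self.coefficients:
            if name not in known:
                raise CovariateError(
                    f"QoL coefficient {name!r} is not in the covariate registry")


@dataclass
class CoefficientSet:
    equations: dict                 # (endpoint, population) -> RiskEquation
    qol: QoLModel
    replicate_id: int = 0
    centring: dict = field(default_factory=lambda: dict(registry.CENTRING_DEFAULTS))

    def __post_init__(self):
        self.validate()

    def validate(self):
        """Every endpoint must resolve for both prevention populations."""
        for endpoint in registry.ENDPOINTS:
            for population in ("no_cvd", "cvd"):
                try:
                    self.equation(endpoint, population)
                except KeyError:
                    raise CoefficientSetError(
                        f"coefficient set incomplete: no equation resolves "
                        f"{endpoint} for population {population!r}") from None
        for key, eq in self.equations.items():
            if key != (eq.endpoint, eq.population):
                raise CoefficientSetError(
                    f"equation stored under {key} declares "
                    f"({eq.endpoint}, {eq.population})")
        for name in registry.CENTRING_DEFAULTS:
            if name not in self.centring:
                raise CoefficientSetError(f"centring constant {name!r} missing")

    def equation(self, endpoint: str, population: str) -> RiskEquation:
        """Resolve the equation for an endpoint and prevention population,
        falling back to a pooled equation where one exists."""
        if (endpoint, population) in self.equations:
            return self.equations[(endpoint, population)]
        return self.equations[(endpoint, "pooled")]

    @property
    def age_centre(self) -> float:
        return self.centring["age"]

    def copy(self, replicate_id=None) -> "CoefficientSet":
        new = deserialize(serialize(self))
        if replicate_id is not None:
            new.replicate_id = replicate_id
        return new


def serialize(cs: CoefficientSet) -> dict:
    return {
        "version": SCHEMA_VERSION,
        "registry_version": registry.REGISTRY_VERSION,
        "replicate_id": cs.replicate_id,
        "centring": dict(cs.centring),
        "equations": [
            {
                "endpoint": eq.endpoint,
                "population": eq.population,
                "baseline": dataclasses.asdict(eq.baseline),
                "coefficients": dict(eq.coefficients),
                "calibration": dataclasses.asdict(eq.calibration),
            }
            for eq in cs.equations.values()
        ],
        "qol": {
            "intercept": cs.qol.intercept,
            "coefficients": dict(cs.qol.coefficients),
            "bounds": list(cs.qol.bounds),
        },
    }


def deserialize(doc: dict) -> CoefficientSet:
    if not isinstance(doc, dict) or "version" not in doc:
        raise CoefficientSetError("coefficient document lacks a version field")
    if doc["version"] != SCHEMA_VERSION:
        raise CoefficientSetError(
            f"unsupported coefficient schema version {doc['version']!r}")
    equations = {}
    for entry in doc.get("equations", []):
        try:
            eq = RiskEquation(
                endpoint=entry["endpoint"],
                population=entry["population"],
                baseline=Baseline(**entry["baseline"]),
                coefficients=dict(entry.get("coefficients", {})),
                calibration=Calibration(**entry.get("calibration", {})),
            )
        except (KeyError, TypeError) as exc:
            raise CoefficientSetError(f"malformed equation entry: {exc}") from exc
        key = (eq.endpoint, eq.population)
        if key in equations:
            raise CoefficientSetError(f"duplicate equation for {key}")
        equations[key] = eq
    qol_doc = doc.get("qol")
    if qol_doc is None:
        raise CoefficientSetError("coefficient document lacks a qol section")
    qol = QoLModel(intercept=qol_doc["intercept"],
                   coefficients=dict(qol_doc.get("coefficients", {})),
                   bounds=tuple(qol_doc.get("bounds",
                                            (registry.EQ5D_FLOOR,
                                             registry.EQ5D_CEILING))))
    centring = dict(registry.CENTRING_DEFAULTS)
    centring.update(doc.get("centring", {}))
    return CoefficientSet(equations=equations, qol=qol,
                          replicate_id=int(doc.get("replicate_id", 0)),
                          centring=centring)


def read_coefficients(path) -> CoefficientSet:
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise CoefficientSetError(f"cannot parse {path}: {exc}") from exc
    return deserialize(doc)


def write_coefficients(cs: CoefficientSet, path):
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(serialize(cs), fh, indent=1, sort_keys=True)
        fh.write("\n")


@dataclass
class ReferencePopulation:
    """Standardization weights by (sex, age_band, deprivation quintile)."""
    weights: dict  # (sex, age_band, quintile) -> nonnegative weight

    def __post_init__(self):
        total = sum(self.weights.values())
        if total <= 0:
            raise CoefficientSetError("reference weights must sum to > 0")
        if any(w < 0 for w in self.weights.values()):
            raise CoefficientSetError("reference weights must be nonnegative")
        self.weights = {k: w / total for k, w in self.weights.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [{"sex": s, "age_band": b, "quintile": q, "weight": w}
                for (s, b, q), w in sorted(self.weights.items())]
        return pd.DataFrame(rows)


def read_reference_population(path) -> ReferencePopulation:
    df = pd.read_csv(path)
    needed = {"sex", "age_band", "quintile", "weight"}
    if not needed.issubset(df.columns):
        raise CoefficientSetError(
            f"reference population file must have columns {sorted(needed)}")
    weights = {(r.sex, str(r.age_band), int(r.quintile)): float(r.weight)
               for r in df.itertuples()}
    return ReferencePopulation(weights=weights)


def write_reference_population(ref: ReferencePopulation, path):
    ref.to_frame().to_csv(path, index=False)
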
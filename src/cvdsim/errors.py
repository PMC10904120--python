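"""Typed exceptions raised across the package.

Validation is total: malformed input always raises one of these, never a
partially constructed object.
"""


class CVDSimError(Exception):
    """Base class for all package errors."""


class CohortSchemaError(CVDSimError):
    """A cohort file is missing a mandatory column or has a malformed header."""


class CohortRowError(CVDSimError):
    """A cohort row holds an out-of-range value or unknown category level."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class CoefficientSetError(CVDSimError):
    """A coefficient file is incomplete, inconsistent or unparseable."""


class CovariateError(CVDSimError):
    """A coefficient references a covariate name absent from the registry,
    or one that cannot be resolved from a profile/state."""


class ConfigError(CVDSimError):
    """Invalid simulation, scenario or CLI configuration."""


class EstimationError(CVDSimError):
    """Risk-equation or QoL fitting failed (no events, rank deficiency,
    non-convergence)."""


class CalibrationError(CVDSimError):
    """Calibration search failed to converge within its iteration budget."""

    def __init__(self, message: str, best_shifts=None):
        self.best_shifts = best_shifts
        super().__init__(message)


class PartitionError(CVDSimError):
    """Category definitions passed to a summary do not partition the cohort."""
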
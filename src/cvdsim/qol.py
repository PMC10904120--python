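"""EQ-5D utility prediction and estimation.

Annual health-related quality of life is a linear function of personal
characteristics and disease history, with event-phase decrements (year of
event vs subsequent years for MI and stroke; diabetes split at 10 years
from diagnosis; any cancer history). Predictions clamp to the EQ-5D-3L
utility range [-0.594, 1], where 0 is equivalent to death.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .coefficients import QoLModel
from .errors import EstimationError
from .profiles import DynamicState, IndividualProfile
from .registry import CENTRING_DEFAULTS, resolve_covariate


def clamp_utility(u: float, bounds=(-0.594, 1.0)) -> float:
    return min(max(u, bounds[0]), bounds[1])


def predict_utility(profile: IndividualProfile, state: DynamicState,
                    qol: QoLModel, centring: dict = None) -> float:
    """Predicted utility for one person-year, clamped to the EQ-5D range."""
    c = centring if centring is not None else CENTRING_DEFAULTS
    u = qol.intercept
    for name, beta in qol.coefficients.items():
        u += beta * resolve_covariate(name, profile, state, c)
    return clamp_utility(u, qol.bounds)


class QoLFitResults:
    """OLS fit of the utility model: point estimates, SEs and diagnostics."""

    def __init__(self, model: QoLModel, bse: dict, sm_results):
        self.model = model
        self.bse = bse                      # name -> standard error
        self._sm = sm_results
        self.nobs = int(sm_results.nobs)
        self.rsquared = float(sm_results.rsquared)

    def summary(self):
        return self._sm.summary()


def fit_qol_model(survey: pd.DataFrame, covariates=None,
                  utility_col: str = "utility") -> QoLFitResults:
    """Fit the linear utility regression by ordinary least squares.

    `survey` holds one row per respondent with a `utility` column and the
    covariate design columns (registry names, already numerically coded).
    Rank deficiency raises an EstimationError naming the collinear columns.
    """
    import statsmodels.api as sm

    if covariates is None:
        covariates = [c for c in survey.columns if c != utility_col]
    if utility_col not in survey.columns:
        raise EstimationError(f"survey lacks a {utility_col!r} column")
    if len(survey) < len(covariates) + 1:
        raise EstimationError("fewer observations than parameters")
    X = survey[list(covariates)].to_numpy(dtype=float)
    if survey[list(covariates)].drop_duplicates().shape[0] < 2:
        raise EstimationError("need >= 2 distinct covariate patterns")
    design = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by incremental rank
        collinear = []
        cols = [np.ones(len(X))]
        for j, name in enumerate(covariates):
            trial = np.column_stack(cols + [X[:, j]])
            if np.linalg.matrix_rank(trial) == len(cols):
                collinear.append(name)
            else:
                cols.append(X[:, j])
        raise EstimationError(f"design matrix rank deficient; "
                              f"collinear columns: {collinear}")
    y = survey[utility_col].to_numpy(dtype=float)
    res = sm.OLS(y, design).fit()
    names = ["intercept"] + list(covariates)
    params = dict(zip(names, res.params))
    bse = dict(zip(names, res.bse))
    model = QoLModel(intercept=params.pop("intercept"),
                     coefficients=params)
    bse_model = {k: v for k, v in bse.items()}
    return QoLFitResults(model=model, bse=bse_model, sm_results=res)
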
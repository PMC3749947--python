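"""Multilinear regression of Erk/Akt activation on HER phosphorylation.

Two linear forms link a downstream target T (phospho-Erk or phospho-Akt)
to receptor-level activity:

* receptor mode:  pT(t) = b0 + sum_i  b_i   * pR_i(t)      (i = HER1..3)
* dimer mode:     pT(t) = b0 + sum_ij b_iji * pR_iji(t)

where pR_iji is the contribution of dimer Rij to the phosphorylation of
receptor i (from :func:`herdyn.analysis.decompose`).  Fitting is ordinary
least squares with an intercept; predictors are z-scored by default so the
absolute coefficients double as an importance ranking.  Collinearity is
reported through the design-matrix condition number, and rank deficiency
is flagged (the fit then follows the minimum-norm pseudoinverse
convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["RegressionSpec", "RegressionResult", "fit_regression"]


@dataclass
class RegressionSpec:
    """Target series and predictor matrix for one regression."""

    target_name: str  # "pErk" | "pAkt" (free-form label)
    mode: str  # "receptor" | "dimer"
    target: pd.Series | np.ndarray = field(repr=False, default=None)
    predictors: pd.DataFrame = field(repr=False, default=None)
    zscore: bool = True

    def __post_init__(self):
        if self.mode not in ("receptor", "dimer"):
            raise ValueError("mode must be 'receptor' or 'dimer'")
        if self.mode == "receptor" and self.predictors.shape[1] != 3:
            raise ValueError(
                "receptor mode uses exactly the 3 predictors pR1, pR2, pR3"
            )
        if len(self.predictors) < self.predictors.shape[1] + 1:
            raise ValueError(
                "need at least n_predictors + 1 observations for the fit"
            )


@dataclass
class RegressionResult:
    """OLS coefficients, fit quality and importance ranking."""

    intercept: float
    coefficients: pd.Series
    r_squared: float
    residuals: np.ndarray
    condition_number: float
    rank_deficient: bool
    ranking: list[str]
    #: scaler (mean, sd) per predictor when z-scoring was applied
    scaling: pd.DataFrame | None = None

    def predict(self, predictors: pd.DataFrame) -> np.ndarray:
        X = predictors[self.coefficients.index].to_numpy(dtype=float)
        if self.scaling is not None:
            X = (X - self.scaling["mean"].to_numpy()) / self.scaling["sd"].to_numpy()
        return self.intercept + X @ self.coefficients.to_numpy()


def fit_regression(spec: RegressionSpec) -> RegressionResult:
    """Ordinary least squares on the stated linear form.

    Constant predictors are harmless (their slope is 0 after z-scoring
    skips zero-variance columns).  A rank-deficient design is fitted with
    the minimum-norm convention and flagged with a warning.
    """
    y = np.asarray(spec.target, dtype=float)
    X = spec.predictors.astype(float).copy()
    names = list(X.columns)
    scaling = None
    if spec.zscore:
        mean = X.mean()
        sd = X.std(ddof=0).replace(0.0, 1.0)  # zero-variance: leave centered
        X = (X - mean) / sd
        scaling = pd.DataFrame({"mean": mean, "sd": sd})
    design = sm.add_constant(X.to_numpy(), has_constant="add")
    model = sm.OLS(y, design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels warns on collinearity
        res = model.fit()
    rank = np.linalg.matrix_rank(design)
    deficient = rank < design.shape[1]
    if deficient:
        warnings.warn(
            "rank-deficient regression design; coefficients follow the "
            "minimum-norm convention", stacklevel=2,
        )
    coefs = pd.Series(res.params[1:], index=names)
    ranking = list(coefs.abs().sort_values(ascending=False).index)
    return RegressionResult(
        intercept=float(res.params[0]),
        coefficients=coefs,
        r_squared=float(res.rsquared) if y.std() > 0 else 1.0,
        residuals=np.asarray(res.resid),
        condition_number=float(np.linalg.cond(design)),
        rank_deficient=bool(deficient),
        ranking=ranking,
        scaling=scaling,
    )
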
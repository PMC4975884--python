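"""Regression engine: logistic fits with average marginal effects of age,
Gaussian linear fits, and the likelihood-ratio linearity check.

The decline rate reported for a binary finding is the **average marginal
effect** (AME) of age: the sample mean of the derivative of the fitted
prevalence with respect to age,

    AME = (100 / n) * sum_i  beta * p_i * (1 - p_i)      [percentage points/year]

with its standard error propagated from the full parameter covariance by the
delta method. For the Gaussian linear model the marginal effect is simply the
slope coefficient. Model fitting itself is delegated to statsmodels
(GLM/Binomial and OLS, maximum likelihood via IRLS); the AME, its
delta-method SE and the likelihood computations are implemented here.
Log-likelihoods are always evaluated on the Bernoulli (per-subject) scale so
that grouped-binomial and expanded representations of the same data are
exactly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import warnings

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .aggregates import PrevalenceAggregate
from .reconstruct import IndividualRecord, binary_counts, records_to_arrays

__all__ = [
    "FitResult",
    "MarginalEffect",
    "LinearityTest",
    "SeparationError",
    "ConvergenceError",
    "fit_logistic",
    "fit_logistic_grouped",
    "fit_gaussian",
    "average_marginal_effect",
    "lr_linearity_test",
]

_GRADIENT_TOL = 1e-8
_MAX_ITER = 50


class SeparationError(RuntimeError):
    """The binary outcome is perfectly separated by age; the MLE diverges."""


class ConvergenceError(RuntimeError):
    """IRLS failed to reach the gradient-norm tolerance."""


@dataclass(frozen=True)
class FitResult:
    """A fitted age regression.

    ``slope``/``se_slope`` are on the model's native scale (log-odds per year
    for logistic, outcome units per year for Gaussian). ``params`` and
    ``cov_params`` carry the full parameter vector and covariance needed for
    delta-method propagation.
    """

    model_kind: str  # "logistic" | "gaussian"
    design: str  # "linear-age" | "age-group-factor"
    slope: float
    se_slope: float
    intercept: float
    loglik: float
    n: int
    params: np.ndarray = field(repr=False)
    cov_params: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "design": self.design,
            "slope": self.slope,
            "se_slope": self.se_slope,
            "intercept": self.intercept,
            "loglik": self.loglik,
            "n": self.n,
        }


@dataclass(frozen=True)
class MarginalEffect:
    """Yearly decline estimate in percentage points per year with 95% CI."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


@dataclass(frozen=True)
class LinearityTest:
    statistic: float
    df: int
    pvalue: float


def _design_matrix(ages: np.ndarray, design: str) -> np.ndarray:
    if design == "linear-age":
        return np.column_stack([np.ones_like(ages), ages])
    if design == "age-group-factor":
        # saturated: one indicator per distinct age, no reference cell
        levels = np.unique(ages)
        return (ages[:, None] == levels[None, :]).astype(float)
    raise ValueError(f"unknown design {design!r}")


def _bernoulli_loglik(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-300, 1 - 1e-16)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _check_ages(ages: np.ndarray, design: str, endpoint: str) -> None:
    if design == "linear-age" and np.unique(ages).size < 2:
        raise ValueError(f"{endpoint}: need >= 2 distinct ages for a linear-age fit")


def fit_logistic(
    records: Sequence[IndividualRecord],
    design: str = "linear-age",
    endpoint: str = "endpoint",
) -> FitResult:
    """Maximum-likelihood logistic regression of a 0/1 outcome on age."""
    ages, y = records_to_arrays(list(records))
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError(f"{endpoint}: logistic outcomes must be 0/1")
    if y.min() == y.max():
        raise SeparationError(f"{endpoint}: all outcomes are {int(y[0])}; no fit possible")
    _check_ages(ages, design, endpoint)
    X = _design_matrix(ages, design)
    return _fit_logistic_matrix(X, y, np.ones_like(y), design, endpoint)


def fit_logistic_grouped(
    aggregate: PrevalenceAggregate, design: str = "linear-age"
) -> FitResult:
    """Logistic fit on (successes, trials) per age group.

    Numerically identical (slope, SE, Bernoulli-scale log-likelihood) to
    :func:`fit_logistic` on the expanded records.
    """
    ages = np.asarray(aggregate.ages)
    counts = np.array([binary_counts(g.n, g.prevalence_pct) for g in aggregate.groups], float)
    k, n = counts[:, 0], counts.sum(axis=1)
    if k.sum() == 0 or k.sum() == n.sum():
        raise SeparationError(f"{aggregate.endpoint}: all outcomes identical; no fit possible")
    _check_ages(ages, design, aggregate.endpoint)
    X = _design_matrix(ages, design)
    # endog = per-group success proportion with var_weights = trials gives the
    # same binomial likelihood kernel as the expanded Bernoulli data
    return _fit_logistic_matrix(X, k / n, n, design, aggregate.endpoint)


def _fit_logistic_matrix(
    X: np.ndarray, y: np.ndarray, weights: np.ndarray, design: str, endpoint: str
) -> FitResult:
    model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=weights)
    try:
        with warnings.catch_warnings():
            # a saturated grouped fit predicts group proportions exactly,
            # which statsmodels also reports as "perfect prediction"; real
            # separation is caught below via the linear predictor
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = model.fit(maxiter=_MAX_ITER, tol=1e-12)
    except PerfectSeparationError as exc:
        raise SeparationError(f"{endpoint}: perfect separation detected") from exc
    p = res.fittedvalues
    score = X.T @ (weights * (y - p))
    # |logit| > 30 means fitted probabilities saturate at 0/1: separation
    if not np.all(np.isfinite(res.params)) or np.abs(X @ res.params).max() > 30:
        raise SeparationError(f"{endpoint}: diverging coefficients indicate separation")
    if np.linalg.norm(score) >= _GRADIENT_TOL * max(1.0, float(weights.sum())):
        raise ConvergenceError(
            f"{endpoint}: IRLS gradient norm {np.linalg.norm(score):.3e} "
            f"after {_MAX_ITER} iterations"
        )
    ll = float(np.sum(weights * (y * np.log(np.clip(p, 1e-300, None))
                                 + (1 - y) * np.log(np.clip(1 - p, 1e-300, None)))))
    if design == "linear-age":
        slope, se = float(res.params[1]), float(res.bse[1])
        intercept = float(res.params[0])
    else:
        slope = se = float("nan")
        intercept = float("nan")
    return FitResult(
        model_kind="logistic",
        design=design,
        slope=slope,
        se_slope=se,
        intercept=intercept,
        loglik=ll,
        n=int(round(float(weights.sum()))),
        params=np.asarray(res.params),
        cov_params=np.asarray(res.cov_params()),
    )


def fit_gaussian(
    records: Sequence[IndividualRecord],
    design: str = "linear-age",
    endpoint: str = "endpoint",
) -> FitResult:
    """Ordinary least squares of a continuous outcome on age.

    The marginal effect of age equals the slope; its SE is the standard OLS
    estimator. The stored log-likelihood is the Gaussian ML value (variance
    estimated by ML), so nested fits are comparable by likelihood ratio.
    """
    ages, y = records_to_arrays(list(records))
    if len(y) < 3:
        raise ValueError(f"{endpoint}: need >= 3 records for a Gaussian fit")
    _check_ages(ages, design, endpoint)
    X = _design_matrix(ages, design)
    res = sm.OLS(y, X).fit()
    if design == "linear-age":
        slope, se, intercept = float(res.params[1]), float(res.bse[1]), float(res.params[0])
        if np.allclose(res.resid, 0.0):
            se = 0.0  # exact fit: zero residual variance
    else:
        slope = se = intercept = float("nan")
    return FitResult(
        model_kind="gaussian",
        design=design,
        slope=slope,
        se_slope=se,
        intercept=intercept,
        loglik=float(res.llf),
        n=int(res.nobs),
        params=np.asarray(res.params),
        cov_params=np.asarray(res.cov_params()),
    )


def average_marginal_effect(
    fit: FitResult, records: Sequence[IndividualRecord]
) -> MarginalEffect:
    """AME of age in percentage points per year, delta-method SE, 95% CI.

    Averages ``beta * p_i * (1 - p_i)`` over the records the model was fitted
    to (the Stata ``margins`` default), then scales by 100. The SE is
    ``sqrt(g' V g)`` where ``g`` is the analytic gradient of the AME with
    respect to (intercept, slope) and ``V`` the estimated covariance.
    """
    if fit.model_kind != "logistic" or fit.design != "linear-age":
        raise ValueError("AME is defined here for linear-age logistic fits")
    ages, _ = records_to_arrays(list(records))
    a, b = fit.params
    p = 1.0 / (1.0 + np.exp(-(a + b * ages)))
    w = p * (1 - p)
    est = 100.0 * float(np.mean(b * w))
    d = 1.0 - 2.0 * p
    grad = np.array(
        [
            100.0 * np.mean(b * w * d),  # d AME / d intercept
            100.0 * np.mean(w + b * ages * w * d),  # d AME / d slope
        ]
    )
    se = float(np.sqrt(grad @ fit.cov_params @ grad))
    return MarginalEffect(est, se, est - 1.96 * se, est + 1.96 * se)


def lr_linearity_test(
    records: Sequence[IndividualRecord],
    saturated_fit: FitResult,
    linear_fit: FitResult,
) -> LinearityTest:
    """Likelihood-ratio test of linear age coding against the saturated model.

    The linear model (intercept + age) is nested in the saturated one (one
    mean per age group); LR = 2 * (ll_saturated - ll_linear) on
    ``#groups - 2`` degrees of freedom. With two age groups the linear model
    is itself saturated: df = 0 and the test is vacuous (p = 1).
    """
    if saturated_fit.design != "age-group-factor" or linear_fit.design != "linear-age":
        raise ValueError("need a saturated (age-group-factor) and a linear-age fit")
    if saturated_fit.model_kind != linear_fit.model_kind:
        raise ValueError("fits are not nested: different model kinds")
    if saturated_fit.n != linear_fit.n:
        raise ValueError("fits are not on identical records")
    ages, _ = records_to_arrays(list(records))
    n_groups = int(np.unique(ages).size)
    lr = 2.0 * (saturated_fit.loglik - linear_fit.loglik)
    if lr < -1e-8:
        raise ValueError(f"negative LR statistic {lr:.3e}: fits are not nested")
    lr = max(lr, 0.0)
    df = n_groups - 2
    pvalue = float(stats.chi2.sf(lr, df)) if df > 0 else 1.0
    return LinearityTest(statistic=lr, df=df, pvalue=pvalue)
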
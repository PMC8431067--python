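"""Concentration-type indices with analytic (robust) standard errors.

The standard concentration index of an outcome *y* against the fractional
income rank *r* is

    CI = 2 cov_w(y, r) / mean_w(y),

twice the weighted covariance over the mean: twice the area between the
concentration curve and the 45-degree line. Positive values mean *y* is
concentrated among the better-off. For a binary outcome the attainable range
is [mean-1, 1-mean], so cross-population comparison uses the Erreygers
correction

    CCI = 4 mean_w(y) CI = 8 cov_w(y, r),

bounded in [-1, 1]. The generalized index GCI = 2 cov_w(v, r) drops the
division by the mean and is defined for mean-zero variables (model residuals).

Standard errors use the convenient-regression device: a transform of y scaled
so that the weighted-least-squares slope on the rank equals the requested
index, with a heteroskedasticity-robust (HC1-type, survey-weight) sandwich
variance for the slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import (DegenerateOutcomeError, InvalidInputError,
                     UndefinedIndexError, UndefinedSEError)


class IndexKind(str, Enum):
    standard_CI = "standard_CI"
    erreygers_CCI = "erreygers_CCI"
    generalized_GCI = "generalized_GCI"


@dataclass
class IndexEstimate:
    """A concentration-type index with optional analytic standard error."""
    kind: IndexKind
    value: float
    se: float | None
    n: int
    mean_y: float
    method: str  # "covariance" or "convenient_regression"


def _check_inputs(y, rank, weight):
    y = np.asarray(y, dtype=float)
    rank = np.asarray(rank, dtype=float)
    weight = np.asarray(weight, dtype=float)
    if not (y.shape == rank.shape == weight.shape) or y.ndim != 1:
        raise InvalidInputError("y, rank and weight must be 1-d vectors of equal length")
    if y.size == 0:
        raise InvalidInputError("empty input")
    if np.any(weight <= 0):
        raise InvalidInputError("all weights must be strictly positive")
    return y, rank, weight


def weighted_mean(x, weight):
    weight = np.asarray(weight, dtype=float)
    return float(np.average(np.asarray(x, dtype=float), weights=weight))


def weighted_cov(x, y, weight):
    """Population-style weighted covariance with normalized weights."""
    w = np.asarray(weight, dtype=float)
    w = w / w.sum()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm = x - np.dot(w, x)
    ym = y - np.dot(w, y)
    return float(np.dot(w, xm * ym))


def concentration_index(y, rank, weight=None, se: bool = False) -> IndexEstimate:
    """Standard concentration index CI = 2 cov_w(y, r) / mean_w(y)."""
    if weight is None:
        weight = np.ones(np.asarray(y).shape)
    y, rank, weight = _check_inputs(y, rank, weight)
    mu = weighted_mean(y, weight)
    if mu == 0.0:
        raise UndefinedIndexError(
            "standard CI undefined: weighted mean of y is zero (division by zero mean)")
    value = 2.0 * weighted_cov(y, rank, weight) / mu
    est = IndexEstimate(IndexKind.standard_CI, value, None, y.size, mu, "covariance")
    if se:
        est.se = index_standard_error(y, rank, weight, IndexKind.standard_CI)
        est.method = "convenient_regression"
    return est


def erreygers_index(y, rank, weight=None, se: bool = False) -> IndexEstimate:
    """Erreygers-corrected concentration index CCI = 8 cov_w(y, r) for binary y."""
    if weight is None:
        weight = np.ones(np.asarray(y).shape)
    y, rank, weight = _check_inputs(y, rank, weight)
    if not np.all((y == 0) | (y == 1)):
        raise InvalidInputError("Erreygers CCI requires a binary 0/1 outcome")
    mu = weighted_mean(y, weight)
    if mu == 0.0 or mu == 1.0:
        raise DegenerateOutcomeError(
            f"CCI undefined: outcome prevalence is {mu:g} (no variation)")
    value = 8.0 * weighted_cov(y, rank, weight)
    est = IndexEstimate(IndexKind.erreygers_CCI, value, None, y.size, mu, "covariance")
    if se:
        est.se = index_standard_error(y, rank, weight, IndexKind.erreygers_CCI)
        est.method = "convenient_regression"
    return est


def generalized_ci(v, rank, weight=None) -> IndexEstimate:
    """Generalized concentration index GCI = 2 cov_w(v, r).

    Defined for any real vector, including mean-zero residuals where the
    standard CI would divide by zero.
    """
    if weight is None:
        weight = np.ones(np.asarray(v).shape)
    v, rank, weight = _check_inputs(v, rank, weight)
    value = 2.0 * weighted_cov(v, rank, weight)
    return IndexEstimate(IndexKind.generalized_GCI, value, None, v.size,
                         weighted_mean(v, weight), "covariance")


def _convenient_regression(lhs, rank, weight):
    """Survey-weighted bivariate WLS of ``lhs`` on ``rank`` with sandwich SE.

    Weights are normalized to sum to n, so value and SE are invariant to
    weight rescaling. The meat uses squared weights (pweight convention) and
    an HC1 small-sample factor n/(n-2).
    """
    n = lhs.size
    w = weight * (n / weight.sum())
    X = np.column_stack([np.ones(n), rank])
    XtW = X.T * w
    A = XtW @ X
    try:
        beta = np.linalg.solve(A, XtW @ lhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - zero rank variance path
        raise UndefinedSEError("convenient regression is singular") from exc
    resid = lhs - X @ beta
    meat = (X * ((w * resid) ** 2)[:, None]).T @ X
    Ainv = np.linalg.inv(A)
    vcov = Ainv @ meat @ Ainv * (n / (n - 2))
    return float(beta[1]), float(np.sqrt(vcov[1, 1]))


def index_standard_error(y, rank, weight, kind: IndexKind) -> float:
    """Robust SE of an index via the convenient regression.

    The left-hand side is scaled so the WLS slope on the rank equals the
    index: ``2 var_w(r) y / mean_w(y)`` for the standard CI,
    ``8 var_w(r) y`` for the Erreygers CCI, ``2 var_w(r) v`` for the GCI.
    """
    y, rank, weight = _check_inputs(y, rank, weight)
    if y.size < 3:
        raise InvalidInputError("need at least 3 observations for a standard error")
    var_r = weighted_cov(rank, rank, weight)
    if var_r <= 0.0:
        raise UndefinedSEError("zero rank variance: SE of the index is undefined")
    kind = IndexKind(kind)
    if kind == IndexKind.standard_CI:
        mu = weighted_mean(y, weight)
        if mu == 0.0:
            raise UndefinedIndexError("standard CI undefined at zero mean")
        lhs = 2.0 * var_r * y / mu
    elif kind == IndexKind.erreygers_CCI:
        lhs = 8.0 * var_r * y
    else:
        lhs = 2.0 * var_r * y
    _, se = _convenient_regression(lhs, rank, weight)
    return se


def convenient_regression_index(y, rank, weight, kind: IndexKind) -> IndexEstimate:
    """Index and robust SE both read off the convenient regression slope.

    Algebraically identical to the covariance forms; exposed so the
    equivalence can be verified and so a single WLS pass yields both value
    and SE.
    """
    y, rank, weight = _check_inputs(y, rank, weight)
    var_r = weighted_cov(rank, rank, weight)
    if var_r <= 0.0:
        raise UndefinedSEError("zero rank variance")
    kind = IndexKind(kind)
    mu = weighted_mean(y, weight)
    if kind == IndexKind.standard_CI:
        if mu == 0.0:
            raise UndefinedIndexError("standard CI undefined at zero mean")
        lhs = 2.0 * var_r * y / mu
    elif kind == IndexKind.erreygers_CCI:
        lhs = 8.0 * var_r * y
    else:
        lhs = 2.0 * var_r * y
    slope, se = _convenient_regression(lhs, rank, weight)
    return IndexEstimate(kind, slope, se, y.size, mu, "convenient_regression")
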
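"""Need / non-need decomposition of the corrected concentration index.

With a linear (or linearized) outcome model
``y_i = a + sum_j m_j x_ji + u_i`` the Erreygers-corrected index decomposes
exactly, by linearity of the covariance, into elasticity-weighted regressor
contributions plus a residual term:

    CCI = sum_j 4 m_j xbar_j CI(x_j) + 4 GCI(u)
        = sum_j 8 m_j cov_w(x_j, r) + 8 cov_w(u, r).

For a probit model the slopes m_j are the partial effects at the weighted
sample means, so the "residual" also carries the linear-approximation error;
it is always reported, never absorbed. The horizontal inequity index is the
part of the CCI that need variables do not explain:

    HI = CCI - sum_{j in need} contribution_j.

Negative HI for an unmet-need outcome means unmet need is concentrated among
the poor beyond what need explains (pro-rich inequity in access); positive HI
is the converse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_model import NEED_COLUMNS, NONNEED_COLUMNS
from .errors import InvalidInputError
from .index_core import erreygers_index, weighted_cov, weighted_mean
from .probit import ProbitFit, build_design, fit_probit, partial_effects_at_means


@dataclass
class Contribution:
    """One regressor's elasticity-weighted contribution to the CCI."""
    name: str
    factor: str            # parent factor (== name for non-categorical columns)
    cls: str               # "need" or "nonneed"
    partial_effect: float  # m_j (probit partial effect at means, or OLS slope)
    mean: float            # weighted mean of the regressor
    partial_ci: float      # standard CI of the regressor against the rank
    contribution: float    # 4 * m_j * mean_j * CI(x_j) == 8 * m_j * cov_w(x_j, r)


@dataclass
class DecompositionResult:
    outcome: str
    group: str
    cci_total: float
    contributions: list[Contribution]
    residual_term: float
    need_sum: float
    nonneed_sum: float
    hi: float
    model: str
    n: int
    fit: ProbitFit | None = field(default=None, repr=False)

    def by_factor(self) -> pd.DataFrame:
        """Roll dummy contributions up to their parent factor."""
        rows = {}
        for c in self.contributions:
            key = (c.factor, c.cls)
            rows[key] = rows.get(key, 0.0) + c.contribution
        return pd.DataFrame(
            [{"factor": f, "class": cls, "contribution": v}
             for (f, cls), v in rows.items()])


def _wls(y, X, w):
    XtW = X.T * w
    beta = np.linalg.solve(XtW @ X, XtW @ y)
    return beta


def decompose_arrays(y, X, names, classes, factor_of, weight, rank,
                     model: str = "probit_approx", outcome: str = "y",
                     group: str = "", start=None) -> DecompositionResult:
    """Decomposition on pre-built arrays (the bootstrap's fast path)."""
    y = np.asarray(y, dtype=float)
    w = np.asarray(weight, dtype=float)
    r = np.asarray(rank, dtype=float)
    cci_total = erreygers_index(y, r, w).value

    fit = None
    if model == "probit_approx":
        fit = fit_probit(y, X, w, names=names, start=start)
        m_full = partial_effects_at_means(fit)
    elif model == "ols":
        m_full = _wls(y, X, w)
    else:
        raise InvalidInputError(f"unknown decomposition model {model!r}")

    xbar = np.average(X, axis=0, weights=w)
    contributions = []
    need_sum = nonneed_sum = 0.0
    for j in range(1, X.shape[1]):
        cov_j = weighted_cov(X[:, j], r, w)
        contrib = 8.0 * m_full[j] * cov_j
        partial_ci = 2.0 * cov_j / xbar[j] if abs(xbar[j]) > 1e-300 else np.nan
        contributions.append(Contribution(
            name=names[j], factor=factor_of[j], cls=classes[j],
            partial_effect=float(m_full[j]), mean=float(xbar[j]),
            partial_ci=float(partial_ci), contribution=float(contrib)))
        if classes[j] == "need":
            need_sum += contrib
        else:
            nonneed_sum += contrib

    slopes = m_full[1:]
    ybar = weighted_mean(y, w)
    alpha_m = ybar - float(slopes @ xbar[1:])  # centers u at zero weighted mean
    u = y - (alpha_m + X[:, 1:] @ slopes)
    residual_term = 8.0 * weighted_cov(u, r, w)  # == 4 * GCI(u)

    hi = cci_total - need_sum
    return DecompositionResult(outcome=outcome, group=group, cci_total=float(cci_total),
                               contributions=contributions,
                               residual_term=float(residual_term),
                               need_sum=float(need_sum),
                               nonneed_sum=float(nonneed_sum),
                               hi=float(hi), model=model, n=y.size, fit=fit)


def decompose(df: pd.DataFrame, outcome: str, need=NEED_COLUMNS,
              nonneed=NONNEED_COLUMNS, weight_col: str = "weight",
              rank_col: str = "frac_rank", model: str = "probit_approx",
              group: str = "") -> DecompositionResult:
    """Decompose the CCI of ``outcome`` for one group's rows.

    ``df`` must already carry fractional ranks (see
    :func:`hequity.data_model.prepare`).
    """
    X, names, classes, factor_of = build_design(df, need, nonneed)
    return decompose_arrays(df[outcome].to_numpy(dtype=float), X, names, classes,
                            factor_of, df[weight_col].to_numpy(dtype=float),
                            df[rank_col].to_numpy(dtype=float), model=model,
                            outcome=outcome, group=group)


def horizontal_inequity(result: DecompositionResult) -> float:
    """HI = CCI - need contributions (definitional)."""
    return result.cci_total - result.need_sum


def hi_indirect_standardization(df: pd.DataFrame, outcome: str, need=NEED_COLUMNS,
                                nonneed=NONNEED_COLUMNS, weight_col: str = "weight",
                                rank_col: str = "frac_rank") -> float:
    """Cross-check HI via indirect standardization.

    Need-predicted utilization is the probit probability with need variables
    at their observed values and non-need variables fixed at their weighted
    means; HI is the CCI of the outcome minus the Erreygers-scale index
    (8 cov_w) of the prediction. Agrees with the subtraction-of-contributions
    HI up to the linear-approximation error of the probit.
    """
    X, names, classes, _ = build_design(df, need, nonneed)
    y = df[outcome].to_numpy(dtype=float)
    w = df[weight_col].to_numpy(dtype=float)
    r = df[rank_col].to_numpy(dtype=float)
    fit = fit_probit(y, X, w, names=names)
    xbar = np.average(X, axis=0, weights=w)
    X_std = X.copy()
    for j, cls in enumerate(classes):
        if cls == "nonneed":
            X_std[:, j] = xbar[j]
    yhat = norm.cdf(X_std @ fit.coefficients)
    cci_y = erreygers_index(y, r, w).value
    return float(cci_y - 8.0 * weighted_cov(yhat, r, w))
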
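"""Survey-weighted probit estimation and partial effects at sample means.

The binary unmet-need outcomes are modelled as

    P(y_i = 1 | x_i) = Phi(x_i' b),

fitted by maximizing the weighted log-likelihood with Newton-Raphson
(Fisher scoring with the expected information, step-halving on likelihood
decrease, and a small ridge fallback for near-singular information
matrices). The variance is the survey-weight sandwich. The decomposition
downstream needs the *partial effects at sample means*: the derivative of
the fitted probability at the vector of weighted regressor means,
``phi(xbar' b) * b_j`` for each slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtri
from scipy.stats import norm

from .data_model import CATEGORICAL_LEVELS
from .errors import (CollinearityError, InvalidInputError, NotConvergedError,
                     SeparationError)

_MAX_INDEX = 35.0  # |x'b| beyond this, Phi saturates in double precision


def build_design(df: pd.DataFrame, need, nonneed):
    """Expand the regressor lists into a design matrix with intercept.

    Categorical columns (per :data:`hequity.data_model.CATEGORICAL_LEVELS`)
    are expanded into dummies against their first-listed reference level;
    everything else enters as a numeric column. Returns
    ``(X, names, classes, factor_of)`` where ``classes[j]`` is "need" /
    "nonneed" ("intercept" for column 0) and ``factor_of[j]`` maps each dummy
    back to its parent factor for per-factor roll-ups.
    """
    n = len(df)
    cols = [np.ones(n)]
    names = ["intercept"]
    classes = ["intercept"]
    factor_of = ["intercept"]
    for cls, varlist in (("need", need), ("nonneed", nonneed)):
        for col in varlist:
            if col in CATEGORICAL_LEVELS:
                levels = CATEGORICAL_LEVELS[col]
                vals = df[col].to_numpy()
                for lev in levels[1:]:
                    cols.append((vals == lev).astype(float))
                    names.append(f"{col}[{lev}]")
                    classes.append(cls)
                    factor_of.append(col)
            else:
                cols.append(pd.to_numeric(df[col]).to_numpy(dtype=float))
                names.append(col)
                classes.append(cls)
                factor_of.append(col)
    X = np.column_stack(cols)
    return X, names, classes, factor_of


@dataclass
class ProbitFit:
    coefficients: np.ndarray
    vcov: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    names: list
    n: int
    xbar: np.ndarray  # weighted regressor means (incl. intercept)

    @property
    def linear_index_at_means(self) -> float:
        return float(self.xbar @ self.coefficients)

    @property
    def partial_effects_at_means(self) -> np.ndarray:
        return partial_effects_at_means(self)


def _check_rank(X, names):
    """QR-based rank check naming aliased columns."""
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    tol = diag.max() * X.shape[1] * np.finfo(float).eps * 100
    aliased = [names[j] for j in range(X.shape[1]) if diag[j] <= tol]
    # QR without pivoting can smear deficiency; confirm with SVD rank
    if np.linalg.matrix_rank(X) < X.shape[1]:
        if not aliased:
            aliased = ["<unidentified linear combination>"]
        raise CollinearityError(aliased)


def probit_loglik_grad(beta, y, X, w):
    """Weighted log-likelihood and analytic gradient (stable in the tails)."""
    xb = np.clip(X @ beta, -500, 500)
    ll = float(np.sum(w * (y * log_ndtr(xb) + (1 - y) * log_ndtr(-xb))))
    logpdf = -0.5 * xb * xb - 0.9189385332046727  # log standard normal density
    mills_pos = np.exp(logpdf - log_ndtr(xb))    # phi/Phi
    mills_neg = np.exp(logpdf - log_ndtr(-xb))   # phi/(1-Phi)
    score = y * mills_pos - (1 - y) * mills_neg  # d ll_i / d(x'b)
    grad = X.T @ (w * score)
    return ll, grad, score, mills_pos * mills_neg


def fit_probit(y, X, weight=None, names=None, max_iter: int = 100,
               grad_tol: float = 1e-8, ll_tol: float = 1e-10,
               start=None) -> ProbitFit:
    """Weighted probit ML fit by Newton-Raphson / Fisher scoring.

    Convergence when the gradient max-norm drops below ``grad_tol`` or the
    relative log-likelihood change below ``ll_tol``. Raises
    :class:`SeparationError` when the linear index diverges (perfect
    separation) and :class:`CollinearityError` for rank-deficient designs.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if weight is None:
        weight = np.ones(y.shape)
    w = np.asarray(weight, dtype=float)
    n, k = X.shape
    if names is None:
        names = [f"x{j}" for j in range(k)]
    if y.shape != (n,) or w.shape != (n,):
        raise InvalidInputError("y, X and weight have inconsistent shapes")
    if np.any(w <= 0):
        raise InvalidInputError("all weights must be strictly positive")
    if not np.all((y == 0) | (y == 1)):
        raise InvalidInputError("probit outcome must be binary 0/1")
    if n <= k:
        raise InvalidInputError(f"n = {n} observations cannot identify {k} parameters")
    _check_rank(X, names)

    w = w * (n / w.sum())  # normalize so inference is invariant to weight scale
    mu = float(np.average(y, weights=w))
    if mu in (0.0, 1.0):
        raise InvalidInputError("degenerate outcome: prevalence is 0 or 1")

    if start is not None:
        beta = np.asarray(start, dtype=float).copy()
    else:
        beta = np.zeros(k)
        is_intercept = [j for j in range(k) if np.all(X[:, j] == 1.0)]
        if is_intercept:
            beta[is_intercept[0]] = ndtri(mu)

    ll, grad, score, info_w = probit_loglik_grad(beta, y, X, w)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        H = (X * (w * info_w)[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            H = H + 1e-8 * np.eye(k)
            step = np.linalg.solve(H, grad)
        # step-halving on likelihood decrease
        scale = 1.0
        for _ in range(30):
            beta_new = beta + scale * step
            ll_new, grad_new, score_new, info_w_new = probit_loglik_grad(beta_new, y, X, w)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:  # pragma: no cover - pathological
            break
        denom = abs(ll) + 1e-12
        rel_change = abs(ll_new - ll) / denom
        beta, ll, grad, score, info_w = beta_new, ll_new, grad_new, score_new, info_w_new
        xb_max = float(np.max(np.abs(X @ beta)))
        if xb_max > _MAX_INDEX and np.max(np.abs(grad)) > grad_tol * 100:
            sd = X.std(axis=0)
            scaled = np.abs(beta) * np.where(sd > 0, sd, 1.0)
            scaled[[j for j in range(k) if np.all(X[:, j] == 1.0)]] = 0.0
            raise SeparationError(names[int(np.argmax(scaled))])
        if np.max(np.abs(grad)) < grad_tol or rel_change < ll_tol:
            converged = True
            break

    # sandwich vcov: expected-information bread, squared-weight score meat
    H = (X * (w * info_w)[:, None]).T @ X
    try:
        Hinv = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        Hinv = np.linalg.inv(H + 1e-8 * np.eye(k))
    meat = (X * ((w * score) ** 2)[:, None]).T @ X
    vcov = Hinv @ meat @ Hinv * (n / max(n - k, 1))

    xbar = np.average(X, axis=0, weights=w)
    return ProbitFit(coefficients=beta, vcov=vcov, loglik=ll, converged=converged,
                     n_iter=it, names=list(names), n=n, xbar=xbar)


def partial_effects_at_means(fit: ProbitFit, xbar=None) -> np.ndarray:
    """Partial effects at the weighted sample means: phi(xbar'b) * b.

    The intercept entry holds the density factor times the intercept, so the
    full vector linearizes the fitted probability around the means. Refuses a
    non-converged fit.
    """
    if not fit.converged:
        raise NotConvergedError("cannot compute partial effects from a non-converged fit")
    if xbar is None:
        xbar = fit.xbar
    idx = float(np.asarray(xbar) @ fit.coefficients)
    return norm.pdf(idx) * fit.coefficients
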
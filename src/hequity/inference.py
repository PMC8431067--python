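"""Inference: analytic normal approximation for the CCI, bias-corrected
bootstrap for the horizontal inequity index, significance stars.

The HI estimator is a non-smooth chain (weighted ranking -> probit ->
decomposition), so its standard error comes from resampling individuals with
replacement within the group and re-running the whole chain per replicate —
including the ranking, which is part of the estimator. Intervals are
bias-corrected percentile (BC): with z0 the normal quantile of the fraction
of replicates below the point estimate, the endpoints are the bootstrap
quantiles at Phi(2 z0 +/- z_{alpha/2}). Replicates that fail (separation,
degenerate resampled outcome) are counted and excluded; a failure share
above 5% flags the result unreliable.

Stars follow the two-sided convention * p<0.1, ** p<0.05, *** p<0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from .data_model import NEED_COLUMNS, NONNEED_COLUMNS, weighted_fractional_rank
from .decomposition import decompose_arrays
from .errors import HequityError, InferenceImpossibleError, InvalidInputError
from .index_core import IndexEstimate
from .probit import build_design


def stars_from_p(p: float) -> str:
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


@dataclass
class InferenceResult:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    level: float
    method: str
    stars: str
    p_value: float
    n_reps: int = 0
    n_failed: int = 0
    seed: int | None = None
    unreliable: bool = False
    intervals: dict = field(default_factory=dict)       # level -> (low, high)
    replicates: np.ndarray | None = field(default=None, repr=False)


def analytic_inference_cci(estimate: IndexEstimate, level: float = 0.95) -> InferenceResult:
    """Normal-approximation interval and p-value from an index and robust SE."""
    if estimate.se is None:
        raise InvalidInputError("no standard error available for analytic inference")
    if not (0.0 < level < 1.0):
        raise InvalidInputError("confidence level must lie in (0, 1)")
    z = abs(estimate.value) / estimate.se if estimate.se > 0 else np.inf
    p = float(2.0 * norm.sf(z))
    zq = float(norm.ppf(0.5 + level / 2.0))
    return InferenceResult(estimate=float(estimate.value), se=float(estimate.se),
                           ci_low=float(estimate.value - zq * estimate.se),
                           ci_high=float(estimate.value + zq * estimate.se),
                           level=level, method="normal_approx",
                           stars=stars_from_p(p), p_value=p)


def bc_interval(replicates, point: float, level: float):
    """Bias-corrected percentile interval from successful replicates."""
    reps = np.sort(np.asarray(replicates, dtype=float))
    b = reps.size
    if b == 0:
        raise InferenceImpossibleError("no successful replicates")
    frac = np.clip(np.mean(reps < point), 1.0 / (b + 1), b / (b + 1.0))
    z0 = ndtri(frac)
    za = ndtri((1.0 - level) / 2.0)
    lo_q = ndtr(2.0 * z0 + za)
    hi_q = ndtr(2.0 * z0 - za)
    return (float(np.quantile(reps, lo_q)), float(np.quantile(reps, hi_q)))


def bootstrap_hi(df, outcome: str, need=NEED_COLUMNS, nonneed=NONNEED_COLUMNS,
                 weight_col: str = "weight", income_col: str = "eq_income",
                 rank_col: str = "frac_rank", model: str = "probit_approx",
                 n_reps: int = 1000, level: float = 0.95, levels=None,
                 seed: int = 0, group: str = "",
                 max_fail_share: float = 0.05) -> InferenceResult:
    """Bootstrap SE and BC confidence interval for the HI of one group.

    Resamples rows with replacement (weights travel with their rows) and
    recomputes ranks, the probit and the decomposition inside every
    replicate. ``levels`` may list extra confidence levels; all intervals are
    derived from the same replicate set and stored in ``result.intervals``.
    Deterministic for a fixed ``seed``.
    """
    if levels is None:
        levels = (level,)
    levels = tuple(sorted(set(float(l) for l in levels) | {float(level)}))

    X, names, classes, factor_of = build_design(df, need, nonneed)
    y = df[outcome].to_numpy(dtype=float)
    w = df[weight_col].to_numpy(dtype=float)
    income = df[income_col].to_numpy(dtype=float)
    rank = (df[rank_col].to_numpy(dtype=float) if rank_col in df.columns
            else weighted_fractional_rank(income, w))
    n = y.size

    point_res = decompose_arrays(y, X, names, classes, factor_of, w, rank,
                                 model=model, outcome=outcome, group=group)
    point = point_res.hi
    start = point_res.fit.coefficients if point_res.fit is not None else None

    rng = np.random.default_rng(seed)
    reps = np.empty(n_reps)
    n_ok = 0
    n_failed = 0
    for _ in range(n_reps):
        idx = rng.integers(0, n, n)
        try:
            w_b = w[idx]
            rank_b = weighted_fractional_rank(income[idx], w_b)
            res = decompose_arrays(y[idx], X[idx], names, classes, factor_of,
                                   w_b, rank_b, model=model, start=start)
            reps[n_ok] = res.hi
            n_ok += 1
        except (HequityError, np.linalg.LinAlgError):
            n_failed += 1
    if n_ok == 0:
        raise InferenceImpossibleError(
            f"all {n_reps} bootstrap replicates failed for group {group!r}")
    reps = reps[:n_ok]

    se = float(np.std(reps, ddof=1)) if n_ok > 1 else float("nan")
    intervals = {lv: bc_interval(reps, point, lv) for lv in levels}
    lo, hi = intervals[float(level)]
    z = abs(point) / se if se > 0 else np.inf
    p = float(2.0 * norm.sf(z))
    return InferenceResult(estimate=float(point), se=se, ci_low=lo, ci_high=hi,
                           level=float(level), method="bias_corrected_percentile",
                           stars=stars_from_p(p), p_value=p, n_reps=n_reps,
                           n_failed=n_failed, seed=seed,
                           unreliable=n_failed > max_fail_share * n_reps,
                           intervals=intervals, replicates=reps)
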
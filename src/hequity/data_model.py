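"""Dataset schema, income equivalization, weighted fractional ranks, validation.

The analysis operates on individual-level survey extracts with one row per
respondent: a group label (country), household net income and household size,
a calibrated cross-sectional sampling weight, two binary unmet-need outcomes
(care postponed by the provider; an appointment asked for and denied), need
regressors (age group, gender, self-assessed health, worsened health, chronic
count, cancer, ADL/IADL limitation counts) and non-need regressors (living
alone, log equivalized income, education, job situation, urban residence).

Income is equivalized with the single-parameter (Buhmann) equivalence scale
``income / hh_size**theta`` and each individual's economic position is the
weighted fractional rank of equivalized income within their group: the
cumulative population (weight) share up to the midpoint of the individual's
own weight, which has weighted mean exactly 1/2 for any weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError

# Categorical regressors and their admissible levels. The first level is the
# reference category dropped when building design matrices.
AGE_LEVELS = ["50-64", "65-69", "70-74", "75-79", "80-84", "85+"]
SAH_LEVELS = ["excellent/very good", "good", "fair", "poor"]
EDUCATION_LEVELS = ["primary", "secondary", "higher"]
JOB_LEVELS = ["inactive", "employed", "unemployed"]

CATEGORICAL_LEVELS: dict[str, list[str]] = {
    "age_group": AGE_LEVELS,
    "sah": SAH_LEVELS,
    "education": EDUCATION_LEVELS,
    "job": JOB_LEVELS,
}

#: Default regressor classification: need variables are legitimate drivers of
#: healthcare use (demography and morbidity); non-need variables capture
#: socio-economic circumstances that should not, under horizontal equity,
#: affect access at equal need.
NEED_COLUMNS = ["age_group", "female", "sah", "worsened_health",
                "chronic", "cancer", "adl", "iadl"]
NONNEED_COLUMNS = ["living_alone", "log_eq_income", "education", "job", "urban"]

OUTCOME_COLUMNS = ["y_postponed", "y_denied"]

BINARY_COLUMNS = ["female", "worsened_health", "cancer", "living_alone", "urban"]
COUNT_COLUMNS = ["chronic", "adl", "iadl"]


def equivalize_income(income_hh, hh_size, theta: float = 0.5):
    """Equivalized income under the single-parameter equivalence scale.

    ``eq = income_hh / hh_size**theta`` with ``theta`` in [0, 1]; theta = 0 is
    household income unadjusted, theta = 1 is per-capita income, and the
    conventional default theta = 0.5 is the square-root scale.
    """
    if not (0.0 <= theta <= 1.0):
        raise InvalidParameterError(f"theta must lie in [0, 1], got {theta}")
    income = np.asarray(income_hh, dtype=float)
    size = np.asarray(hh_size, dtype=float)
    if np.any(size < 1):
        raise InvalidParameterError("household size must be >= 1")
    if np.any(income < 0):
        raise InvalidParameterError("household income must be non-negative")
    out = income / size ** theta
    if out.ndim == 0:
        return float(out)
    return out


def weighted_fractional_rank(income, weight):
    """Weighted fractional rank of each unit in the income distribution.

    After sorting by income ascending, unit *i* receives rank
    ``(W_below + w_i/2) / W_total`` where ``W_below`` is the total weight of
    strictly poorer units. Tied incomes are treated as one block and all
    receive the block's midpoint rank, so the result is invariant to input
    order. The weighted mean of the returned ranks is exactly 1/2.
    """
    income = np.asarray(income, dtype=float)
    weight = np.asarray(weight, dtype=float)
    if income.ndim != 1 or weight.ndim != 1 or income.shape != weight.shape:
        raise InvalidInputError("income and weight must be 1-d vectors of equal length")
    if income.size == 0:
        raise InvalidInputError("cannot rank an empty vector")
    if not np.all(np.isfinite(income)) or not np.all(np.isfinite(weight)):
        raise InvalidInputError("income and weight must be finite")
    if np.any(weight <= 0):
        raise InvalidInputError("all weights must be strictly positive")

    order = np.argsort(income, kind="mergesort")
    inc_s = income[order]
    w_s = weight[order]
    # collapse tied incomes into blocks; each block gets its weight-span midpoint
    new_block = np.r_[True, inc_s[1:] != inc_s[:-1]]
    block_id = np.cumsum(new_block) - 1
    block_w = np.bincount(block_id, weights=w_s)
    block_rank = (np.cumsum(block_w) - block_w / 2.0) / w_s.sum()
    ranks = np.empty_like(inc_s)
    ranks[order] = block_rank[block_id]
    return ranks


def prepare(df: pd.DataFrame, theta: float = 0.5, group_col: str = "group",
            income_col: str = "income_hh", size_col: str = "hh_size",
            weight_col: str = "weight") -> pd.DataFrame:
    """Append derived columns: ``eq_income``, ``log_eq_income``, ``frac_rank``.

    Ranks are computed within each group (country) separately, since all
    downstream analyses are per-country. Rows with non-positive equivalized
    income get a missing ``log_eq_income`` (dropped later by complete-case
    validation).
    """
    out = df.copy()
    out["eq_income"] = equivalize_income(out[income_col].to_numpy(),
                                         out[size_col].to_numpy(), theta)
    eq = out["eq_income"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log_eq_income"] = np.where(eq > 0, np.log(np.where(eq > 0, eq, 1.0)), np.nan)
    rank = np.full(len(out), np.nan)
    for _, idx in out.groupby(group_col, sort=False, observed=True).indices.items():
        rank[idx] = weighted_fractional_rank(eq[idx], out[weight_col].to_numpy()[idx])
    out["frac_rank"] = rank
    return out


def n_design_params(need=NEED_COLUMNS, nonneed=NONNEED_COLUMNS) -> int:
    """Number of free parameters (incl. intercept) of the outcome model."""
    k = 1
    for col in list(need) + list(nonneed):
        k += len(CATEGORICAL_LEVELS[col]) - 1 if col in CATEGORICAL_LEVELS else 1
    return k


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_dataset`.

    ``clean`` holds the complete-case rows with valid values only;
    ``unestimable_groups`` lists groups too small for the requested model
    (fewer rows than parameters + 1) — they are kept in ``clean`` but must be
    excluded from model-based operations.
    """
    clean: pd.DataFrame
    n_input: int
    n_dropped: int
    missing_by_column: dict = field(default_factory=dict)
    invalid_by_column: dict = field(default_factory=dict)
    group_sizes: dict = field(default_factory=dict)
    unestimable_groups: list = field(default_factory=list)
    messages: list = field(default_factory=list)


def validate_dataset(df: pd.DataFrame, outcomes=OUTCOME_COLUMNS,
                     need=NEED_COLUMNS, nonneed=NONNEED_COLUMNS,
                     group_col: str = "group", weight_col: str = "weight",
                     income_col: str = "income_hh", size_col: str = "hh_size",
                     ) -> ValidationReport:
    """Complete-case validation of an analysis extract.

    Reports per-column missingness and out-of-range values, drops every row
    with a missing or invalid outcome, income, weight or regressor, and flags
    groups with fewer rows than regression parameters + 1 as unestimable
    (a warning, never a crash).
    """
    required = [group_col, income_col, size_col, weight_col, *outcomes,
                *need, *nonneed]
    required = [c for c in required if c != "log_eq_income" or c in df.columns]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise InvalidInputError(f"dataset is missing required columns: {missing_cols}")

    n_input = len(df)
    bad = pd.Series(False, index=df.index)
    missing_by_column: dict[str, int] = {}
    invalid_by_column: dict[str, int] = {}

    for col in required:
        isna = df[col].isna()
        if isna.any():
            missing_by_column[col] = int(isna.sum())
        bad |= isna

    def _flag(col, mask, label):
        mask = mask.fillna(False)
        if mask.any():
            invalid_by_column[col] = invalid_by_column.get(col, 0) + int(mask.sum())
        return mask

    for col in outcomes:
        bad |= _flag(col, ~df[col].isin([0, 1]), "invalid-outcome")
    bad |= _flag(weight_col, df[weight_col] <= 0, "non-positive weight")
    bad |= _flag(income_col, df[income_col] < 0, "negative income")
    bad |= _flag(size_col, df[size_col] < 1, "household size < 1")
    for col in COUNT_COLUMNS:
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad |= _flag(col, (vals < 0) | (vals != np.floor(vals)), "invalid count")
    for col in BINARY_COLUMNS:
        if col in df.columns:
            bad |= _flag(col, ~df[col].isin([0, 1]), "non-binary value")
    for col, levels in CATEGORICAL_LEVELS.items():
        if col in df.columns:
            bad |= _flag(col, ~df[col].isin(levels), "unknown category")

    clean = df.loc[~bad].copy()
    n_dropped = n_input - len(clean)

    k = n_design_params(need, nonneed)
    group_sizes = clean.groupby(group_col, observed=True).size().to_dict()
    unestimable = sorted(g for g, n in group_sizes.items() if n < k + 1)

    messages = []
    if n_dropped:
        messages.append(f"dropped {n_dropped} of {n_input} rows (complete-case filtering)")
    for g in unestimable:
        messages.append(
            f"group {g!r} has {group_sizes[g]} rows < {k + 1} required for "
            f"{k} parameters; flagged unestimable")
    return ValidationReport(clean=clean, n_input=n_input, n_dropped=n_dropped,
                            missing_by_column=missing_by_column,
                            invalid_by_column=invalid_by_column,
                            group_sizes=group_sizes,
                            unestimable_groups=unestimable,
                            messages=messages)


def load_dataset(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a delimited extract; ``column_map`` renames source → schema names."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    return df
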
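"""Batch analysis: per-group, per-outcome corrected concentration indices and
horizontal inequity with inference, mirroring a per-country survey analysis.

For every group (country) and every binary unmet-need outcome the runner
computes the Erreygers-corrected concentration index with its analytic robust
standard error, the probit-based need/non-need decomposition, and the
horizontal inequity index with bias-corrected bootstrap intervals. Groups
that fail (degenerate outcome, separation, too few rows) become NA rows with
a reason — a batch never aborts because one country is sick.

Per-group bootstrap seeds are derived from the master seed and the group
label (a stable hash), so adding a country to the batch does not perturb any
other country's results.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import (NEED_COLUMNS, NONNEED_COLUMNS, OUTCOME_COLUMNS,
                         load_dataset, prepare, validate_dataset)
from .decomposition import decompose
from .errors import (CollinearityError, DegenerateOutcomeError, HequityError,
                     InvalidParameterError, SeparationError)
from .index_core import erreygers_index
from .inference import analytic_inference_cci, bootstrap_hi, stars_from_p


@dataclass
class AnalysisSpec:
    """Declarative description of one batch run."""
    outcomes: list = field(default_factory=lambda: list(OUTCOME_COLUMNS))
    need: list = field(default_factory=lambda: list(NEED_COLUMNS))
    nonneed: list = field(default_factory=lambda: list(NONNEED_COLUMNS))
    model: str = "probit_approx"
    n_boot: int = 1000
    levels: list = field(default_factory=lambda: [0.95])
    theta: float = 0.5
    seed: int = 12345
    group_col: str = "group"
    weight_col: str = "weight"
    column_map: dict = field(default_factory=dict)

    def __post_init__(self):
        need, nonneed = set(self.need), set(self.nonneed)
        if need & nonneed:
            raise InvalidParameterError(
                f"need and non-need regressors overlap: {sorted(need & nonneed)}")
        if set(self.outcomes) & (need | nonneed):
            raise InvalidParameterError("an outcome cannot also be a regressor")
        if self.model not in ("probit_approx", "ols"):
            raise InvalidParameterError(f"unknown model {self.model!r}")
        if self.n_boot < 1:
            raise InvalidParameterError("n_boot must be >= 1")
        for lv in self.levels:
            if not 0.0 < lv < 1.0:
                raise InvalidParameterError(f"confidence level {lv} outside (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisSpec":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        return cls(**raw)

    def content_hash(self) -> str:
        return hashlib.md5(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def group_seed(master_seed: int, group: str) -> int:
    """Stable per-group seed below 2**31, independent of batch composition."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(str(group).encode())])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


_REASONS = {
    DegenerateOutcomeError: "degenerate-outcome",
    SeparationError: "separation",
    CollinearityError: "collinearity",
}


def _failure_reason(exc) -> str:
    for klass, label in _REASONS.items():
        if isinstance(exc, klass):
            return label
    return type(exc).__name__


def run_analysis(data, spec: AnalysisSpec, output_dir=None):
    """Run the full batch; returns (results, decomposition_long, log_lines).

    ``data`` is a CSV path or a DataFrame in the schema of
    :mod:`hequity.data_model`. When ``output_dir`` is given, writes
    ``results.csv`` (full precision), ``results_rounded.csv`` (4 decimals),
    ``decomposition.csv`` and ``run.log`` there.
    """
    df = load_dataset(data, spec.column_map) if not isinstance(data, pd.DataFrame) \
        else (data.rename(columns=spec.column_map) if spec.column_map else data)
    report = validate_dataset(df, outcomes=spec.outcomes, need=spec.need,
                              nonneed=spec.nonneed, group_col=spec.group_col,
                              weight_col=spec.weight_col)
    prepared = prepare(report.clean, theta=spec.theta, group_col=spec.group_col,
                       weight_col=spec.weight_col)
    # complete-case on derived regressors (e.g. log income undefined at 0)
    model_cols = [c for c in spec.need + spec.nonneed if c in prepared.columns]
    prepared = prepared.dropna(subset=model_cols + ["frac_rank"])

    log = [f"hequity {__version__} | spec hash {spec.content_hash()} | "
           f"master seed {spec.seed}"]
    log.extend(report.messages)

    rows = []
    decomp_rows = []
    levels = sorted(set(spec.levels))
    primary_level = max(levels)
    for group, gdf in prepared.groupby(spec.group_col, sort=True, observed=True):
        seed_g = group_seed(spec.seed, group)
        for outcome in spec.outcomes:
            t0 = time.perf_counter()
            row = {"group": group, "outcome": outcome, "n": len(gdf),
                   "seed": seed_g, "reason": ""}
            if group in report.unestimable_groups:
                row["reason"] = "unestimable-group"
                rows.append(row)
                log.append(f"{group}/{outcome}: skipped (unestimable-group)")
                continue
            try:
                w = gdf[spec.weight_col].to_numpy(dtype=float)
                y = gdf[outcome].to_numpy(dtype=float)
                r = gdf["frac_rank"].to_numpy(dtype=float)
                cci = erreygers_index(y, r, w, se=True)
                cci_inf = analytic_inference_cci(cci, level=primary_level)
                dec = decompose(gdf, outcome, need=spec.need, nonneed=spec.nonneed,
                                weight_col=spec.weight_col, model=spec.model,
                                group=str(group))
                hi_inf = bootstrap_hi(gdf, outcome, need=spec.need,
                                      nonneed=spec.nonneed,
                                      weight_col=spec.weight_col,
                                      model=spec.model, n_reps=spec.n_boot,
                                      level=primary_level, levels=levels,
                                      seed=seed_g, group=str(group))
                row.update({
                    "prevalence": cci.mean_y,
                    "cci": cci.value, "cci_se": cci.se,
                    "cci_p": cci_inf.p_value, "cci_stars": cci_inf.stars,
                    "hi": hi_inf.estimate, "hi_se": hi_inf.se,
                    "hi_p": hi_inf.p_value, "hi_stars": hi_inf.stars,
                    "need_sum": dec.need_sum, "residual_term": dec.residual_term,
                    "boot_failed": hi_inf.n_failed,
                    "boot_unreliable": hi_inf.unreliable,
                })
                for lv in levels:
                    lo, hi = hi_inf.intervals[lv]
                    pct = int(round(lv * 100))
                    row[f"hi_ci{pct}_low"] = lo
                    row[f"hi_ci{pct}_high"] = hi
                for c in dec.contributions:
                    decomp_rows.append({"group": group, "outcome": outcome,
                                        "regressor": c.name, "factor": c.factor,
                                        "class": c.cls,
                                        "partial_effect": c.partial_effect,
                                        "mean": c.mean, "partial_ci": c.partial_ci,
                                        "contribution": c.contribution})
                decomp_rows.append({"group": group, "outcome": outcome,
                                    "regressor": "<residual>", "factor": "<residual>",
                                    "class": "residual", "partial_effect": np.nan,
                                    "mean": np.nan, "partial_ci": np.nan,
                                    "contribution": dec.residual_term})
                log.append(f"{group}/{outcome}: ok in {time.perf_counter() - t0:.2f}s "
                           f"(seed {seed_g}, {hi_inf.n_failed}/{spec.n_boot} "
                           f"replicates failed)")
            except (HequityError, np.linalg.LinAlgError) as exc:
                row["reason"] = _failure_reason(exc)
                log.append(f"{group}/{outcome}: failed ({row['reason']}: {exc})")
            rows.append(row)

    results = pd.DataFrame(rows)
    decomposition = pd.DataFrame(decomp_rows)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "results.csv", index=False)
        results.round(4).to_csv(out / "results_rounded.csv", index=False)
        decomposition.to_csv(out / "decomposition.csv", index=False)
        (out / "run.log").write_text("\n".join(log) + "\n")
    return results, decomposition, log


def summarize_results(results: pd.DataFrame, levels=(0.95,)) -> pd.DataFrame:
    """Significance summary: which groups show significant CCI / HI per
    outcome at each level, with the sign read as concentration among the
    better-off (positive) or worse-off (negative)."""
    rows = []
    for lv in levels:
        alpha = 1.0 - lv
        for _, r in results.iterrows():
            reason = r.get("reason", "")
            if isinstance(reason, str) and reason:
                continue
            for measure in ("cci", "hi"):
                p = r.get(f"{measure}_p")
                if p is None or pd.isna(p) or p >= alpha:
                    continue
                est = r[measure]
                rows.append({"level": lv, "group": r["group"],
                             "outcome": r["outcome"], "measure": measure,
                             "estimate": est, "p_value": p,
                             "stars": stars_from_p(p),
                             "direction": ("concentrated among better-off"
                                           if est > 0 else
                                           "concentrated among worse-off")})
    return pd.DataFrame(rows, columns=["level", "group", "outcome", "measure",
                                       "estimate", "p_value", "stars", "direction"])
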
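"""Synthetic SHARE-like survey extracts from a fully specified probit DGP.

The generator emulates the schema of a European survey of adults aged 50+
during the first COVID-19 wave: household income and size, calibrated
weights, demography (age bands 50-95, gender), morbidity (self-assessed
health, worsened health, chronic count, cancer, ADL/IADL limitations),
socio-economic status (education, job situation, living alone, urban) and
two binary unmet-need outcomes (postponed care, denied appointment) drawn
from a probit latent-index model

    y* = alpha + x'beta (need) + z'gamma (non-need) + delta * ln(eq income, centered) + eps,
    y = 1{y* > 0},   eps ~ N(0, 1).

Income-related inequity beyond need is injected only through delta and
gamma: with delta = 0 and gamma = 0 the true horizontal inequity is zero,
while need variables may still carry an income gradient (self-assessed
health worsens with lower income), producing a nonzero total concentration
index that the decomposition must attribute to need. Covariate dependence
(age -> health -> limitations, income -> education) runs through explicit
linear-index links so every regressor class is exercised with controlled
correlation against the income rank.

Everything is deterministic given the scenario seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .data_model import (AGE_LEVELS, EDUCATION_LEVELS, JOB_LEVELS, SAH_LEVELS,
                         equivalize_income)
from .errors import InvalidParameterError

_AGE_BANDS = [(50, 65), (65, 70), (70, 75), (75, 80), (80, 85), (85, 96)]


@dataclass
class OutcomeModel:
    """Probit coefficients for one binary unmet-need outcome.

    ``need`` and ``nonneed`` are keyed by design column names (dummy columns
    as ``factor[level]``); ``delta`` is the direct slope on centered log
    equivalized income — the injected income-related inequity at equal need.
    """
    alpha: float
    need: dict = field(default_factory=dict)
    nonneed: dict = field(default_factory=dict)
    delta: float = 0.0


@dataclass
class ScenarioConfig:
    """Full parameterization of the data-generating process."""
    name: str = "custom"
    n_per_group: int = 2000
    groups: tuple = ("A",)
    seed: int = 12345
    # income: lognormal household income, per group or shared
    income_location: float | dict = 9.81   # mean of ln(household income)
    income_scale: float | dict = 0.77      # sd of ln(household income)
    theta: float = 0.5                     # equivalence-scale power
    hh_size_probs: tuple = (0.28, 0.55, 0.09, 0.05, 0.03)   # sizes 1..5
    weight_low: float = 0.5
    weight_high: float = 1.5
    # demography
    age_group_probs: tuple = (0.473, 0.136, 0.132, 0.096, 0.089, 0.074)
    female_p: float = 0.546
    # self-assessed health: ordered latent on age and income
    sah_age_slope: float = 0.45
    sah_income_slope: float = -0.35
    sah_cuts: tuple = (-0.784, 0.647, 1.773)
    worsened_base: float = -1.70
    worsened_sah_slope: float = 0.30
    chronic_log_base: float = 0.585
    chronic_age_slope: float = 0.03
    cancer_p: float = 0.037
    adl_base_p: float = 0.12
    adl_age_slope: float = 0.004
    adl_extra_mean: float = 0.5
    iadl_base_p: float = 0.18
    iadl_age_slope: float = 0.006
    iadl_extra_mean: float = 0.85
    # socio-economic
    edu_income_slope: float = 0.8
    edu_cuts: tuple = (-0.466, 0.985)
    job_probs_young: tuple = (0.25, 0.62, 0.13)   # inactive, employed, unemployed
    job_probs_old: tuple = (0.92, 0.05, 0.03)
    urban_p: float = 0.619
    # outcome models keyed by outcome column name
    outcomes: dict = field(default_factory=dict)
    error_dist: str = "normal"   # "logistic" toggles a misspecified link

    def __post_init__(self):
        for p in (self.female_p, self.cancer_p, self.urban_p,
                  self.adl_base_p, self.iadl_base_p):
            if not 0.0 <= p <= 1.0:
                raise InvalidParameterError(f"probability {p} outside [0, 1]")
        for probs in (self.hh_size_probs, self.age_group_probs,
                      self.job_probs_young, self.job_probs_old):
            arr = np.asarray(probs, dtype=float)
            if np.any(arr < 0) or not math.isclose(arr.sum(), 1.0, abs_tol=1e-8):
                raise InvalidParameterError(
                    f"probabilities {probs} must be non-negative and sum to 1")
        for scale in np.atleast_1d(self._per_group_array("income_scale")):
            if scale <= 0:
                raise InvalidParameterError("income scale must be positive")
        if not (0 < self.weight_low <= self.weight_high):
            raise InvalidParameterError("weight bounds must satisfy 0 < low <= high")
        if self.error_dist not in ("normal", "logistic"):
            raise InvalidParameterError(f"unknown error distribution {self.error_dist!r}")
        if self.n_per_group < 1:
            raise InvalidParameterError("n_per_group must be >= 1")

    def _per_group_array(self, attr):
        val = getattr(self, attr)
        if isinstance(val, dict):
            return np.array([float(val[g]) for g in self.groups])
        return np.full(len(self.groups), float(val))

    def log_eq_income_center(self, group) -> float:
        """Exact mean of ln(equivalized income) implied by the config."""
        loc = self.income_location[group] if isinstance(self.income_location, dict) \
            else self.income_location
        sizes = np.arange(1, 6)
        mean_log_size = float(np.dot(self.hh_size_probs, np.log(sizes)))
        return float(loc) - self.theta * mean_log_size

    def log_eq_income_sd(self, group) -> float:
        scale = self.income_scale[group] if isinstance(self.income_scale, dict) \
            else self.income_scale
        sizes = np.arange(1, 6)
        logs = np.log(sizes)
        mls = float(np.dot(self.hh_size_probs, logs))
        var_log_size = float(np.dot(self.hh_size_probs, (logs - mls) ** 2))
        return math.sqrt(float(scale) ** 2 + self.theta ** 2 * var_log_size)


def _linear_index(model: OutcomeModel, cols: dict, log_eq_centered) -> np.ndarray:
    idx = np.full_like(log_eq_centered, model.alpha)
    for coefs in (model.need, model.nonneed):
        for name, b in coefs.items():
            if name not in cols:
                raise InvalidParameterError(f"unknown regressor {name!r} in outcome model")
            idx = idx + b * cols[name]
    return idx + model.delta * log_eq_centered


def generate_dataset(config: ScenarioConfig, n_per_group: int | None = None,
                     seed: int | None = None) -> pd.DataFrame:
    """Draw a schema-complete extract for every group in the scenario."""
    n = int(n_per_group if n_per_group is not None else config.n_per_group)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    frames = []
    offset = 0
    for g in config.groups:
        frames.append(_generate_group(config, g, n, rng, offset))
        offset += n
    return pd.concat(frames, ignore_index=True)


def _generate_group(config, group, n, rng, id_offset):
    loc = config.income_location[group] if isinstance(config.income_location, dict) \
        else config.income_location
    scale = config.income_scale[group] if isinstance(config.income_scale, dict) \
        else config.income_scale

    income_hh = np.exp(rng.normal(float(loc), float(scale), n))
    hh_size = rng.choice(np.arange(1, 6), size=n, p=config.hh_size_probs)
    weight = rng.uniform(config.weight_low, config.weight_high, n)

    band = rng.choice(len(_AGE_BANDS), size=n, p=config.age_group_probs)
    lo = np.array([_AGE_BANDS[b][0] for b in band], dtype=float)
    hi = np.array([_AGE_BANDS[b][1] for b in band], dtype=float)
    age = lo + rng.random(n) * (hi - lo)
    age_group = np.array(AGE_LEVELS, dtype=object)[band]
    z_age = (age - 68.0) / 10.0

    female = (rng.random(n) < config.female_p).astype(int)

    eq_income = equivalize_income(income_hh, hh_size, config.theta)
    log_eq = np.log(eq_income)
    center = config.log_eq_income_center(group)
    sd_log = config.log_eq_income_sd(group)
    z_inc = (log_eq - center) / sd_log

    sah_latent = (config.sah_age_slope * z_age + config.sah_income_slope * z_inc
                  + rng.standard_normal(n))
    sah_idx = np.digitize(sah_latent, config.sah_cuts)
    sah = np.array(SAH_LEVELS, dtype=object)[sah_idx]

    worsened = (rng.random(n) <
                ndtr(config.worsened_base + config.worsened_sah_slope * sah_idx)
                ).astype(int)
    chronic = rng.poisson(np.exp(config.chronic_log_base
                                 + config.chronic_age_slope * (age - 68.0)))
    cancer = (rng.random(n) < config.cancer_p).astype(int)

    def _zi_count(base_p, age_slope, extra_mean):
        p_pos = np.clip(base_p + age_slope * (age - 68.0), 0.005, 0.8)
        pos = rng.random(n) < p_pos
        return np.where(pos, 1 + rng.poisson(extra_mean, n), 0)

    adl = _zi_count(config.adl_base_p, config.adl_age_slope, config.adl_extra_mean)
    iadl = _zi_count(config.iadl_base_p, config.iadl_age_slope, config.iadl_extra_mean)

    living_alone = (hh_size == 1).astype(int)
    edu_latent = config.edu_income_slope * z_inc + rng.standard_normal(n)
    education = np.array(EDUCATION_LEVELS, dtype=object)[
        np.digitize(edu_latent, config.edu_cuts)]
    young = age < 65
    job_idx = np.where(
        young,
        rng.choice(3, size=n, p=config.job_probs_young),
        rng.choice(3, size=n, p=config.job_probs_old))
    job = np.array(JOB_LEVELS, dtype=object)[job_idx]
    urban = (rng.random(n) < config.urban_p).astype(int)

    # design columns the outcome models may reference
    cols = {"female": female, "worsened_health": worsened, "chronic": chronic,
            "cancer": cancer, "adl": adl, "iadl": iadl,
            "living_alone": living_alone, "urban": urban}
    for lev, name in zip(range(1, 6), AGE_LEVELS[1:]):
        cols[f"age_group[{name}]"] = (band == lev).astype(float)
    for lev, name in enumerate(SAH_LEVELS[1:], start=1):
        cols[f"sah[{name}]"] = (sah_idx == lev).astype(float)
    for lev, name in enumerate(EDUCATION_LEVELS[1:], start=1):
        cols[f"education[{name}]"] = (np.digitize(edu_latent, config.edu_cuts) == lev
                                      ).astype(float)
    for lev, name in enumerate(JOB_LEVELS[1:], start=1):
        cols[f"job[{name}]"] = (job_idx == lev).astype(float)

    log_eq_centered = log_eq - center
    data = {"unit_id": np.arange(id_offset, id_offset + n),
            "group": group, "income_hh": income_hh, "hh_size": hh_size,
            "weight": weight, "age": age, "age_group": age_group,
            "female": female, "sah": sah, "worsened_health": worsened,
            "chronic": chronic, "cancer": cancer, "adl": adl, "iadl": iadl,
            "living_alone": living_alone, "education": education, "job": job,
            "urban": urban}
    for outcome, model in config.outcomes.items():
        idx = _linear_index(model, cols, log_eq_centered)
        if config.error_dist == "normal":
            eps = rng.standard_normal(n)
        else:
            eps = rng.logistic(0.0, math.sqrt(3.0) / math.pi, n)
        data[outcome] = (idx + eps > 0).astype(int)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Preset scenarios
# ---------------------------------------------------------------------------

# Need slopes: a plausible morbidity gradient in the probability of having a
# medical appointment affected during the outbreak (sicker and older people
# have more appointments at stake).
_NEED_SLOPES = {
    "age_group[65-69]": 0.05, "age_group[70-74]": 0.08, "age_group[75-79]": 0.10,
    "age_group[80-84]": 0.10, "age_group[85+]": 0.08,
    "female": 0.10,
    "sah[good]": 0.12, "sah[fair]": 0.25, "sah[poor]": 0.40,
    "worsened_health": 0.30, "chronic": 0.08, "cancer": 0.30,
    "adl": 0.05, "iadl": 0.06,
}

_NONNEED_SLOPES = {
    "living_alone": 0.04, "education[secondary]": 0.05, "education[higher]": 0.08,
    "job[employed]": 0.05, "job[unemployed]": 0.08, "urban": 0.06,
}

# Probit intercepts calibrated once (n = 500k draws) so each preset hits its
# target prevalence: postponed ~ 0.2533, denied ~ 0.0540 (pooled survey means).
_ALPHAS = {
    "share_like": {"y_postponed": -1.2410, "y_denied": -2.2164},
    "null_need_only": {"y_postponed": -1.1426, "y_denied": -2.1095},
    "pro_rich_denial": {"y_postponed": -1.1426, "y_denied": -2.1519},
    "pro_poor_postponement": {"y_postponed": -1.1446, "y_denied": -2.1095},
}


def preset_scenarios(n_per_group: int = 2000, groups=("A",), seed: int = 12345
                     ) -> dict[str, ScenarioConfig]:
    """Named scenarios with known true inequity structure.

    - ``null_need_only``: delta = 0 and gamma = 0 — zero true inequity beyond
      need; need variables still carry an income gradient through SAH.
    - ``pro_rich_denial``: delta < 0 on denied care — the poor are denied
      more at equal need (negative HI).
    - ``pro_poor_postponement``: postponement loads positively on income
      (positive HI).
    - ``share_like``: prevalences and covariate mix near the pooled survey
      means (postponed ~0.25, denied ~0.054, female ~0.55, mean age ~68).
    """
    base = dict(n_per_group=n_per_group, groups=tuple(groups), seed=seed)

    def _outcomes(preset, nonneed, deltas):
        return {out: OutcomeModel(alpha=_ALPHAS[preset][out],
                                  need=dict(_NEED_SLOPES),
                                  nonneed=dict(nonneed),
                                  delta=deltas.get(out, 0.0))
                for out in ("y_postponed", "y_denied")}

    return {
        "share_like": ScenarioConfig(
            name="share_like",
            outcomes=_outcomes("share_like", _NONNEED_SLOPES, {}), **base),
        "null_need_only": ScenarioConfig(
            name="null_need_only",
            outcomes=_outcomes("null_need_only", {}, {}), **base),
        "pro_rich_denial": ScenarioConfig(
            name="pro_rich_denial",
            outcomes=_outcomes("pro_rich_denial", {}, {"y_denied": -0.25}), **base),
        "pro_poor_postponement": ScenarioConfig(
            name="pro_poor_postponement",
            outcomes=_outcomes("pro_poor_postponement", {}, {"y_postponed": 0.12}),
            **base),
    }


def get_scenario(name: str, n_per_group: int = 2000, groups=("A",),
                 seed: int = 12345) -> ScenarioConfig:
    presets = preset_scenarios(n_per_group=n_per_group, groups=groups, seed=seed)
    if name not in presets:
        raise InvalidParameterError(
            f"unknown scenario {name!r}; available: {sorted(presets)}")
    return presets[name]
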
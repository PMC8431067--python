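"""Need/non-need decomposition of the CCI and the horizontal inequity index."""

import numpy as np
import pytest

from hequity import (decompose, erreygers_index, generate_dataset, get_scenario,
                     hi_indirect_standardization, horizontal_inequity, prepare,
                     weighted_fractional_rank)
from hequity.decomposition import decompose_arrays


def random_instance(rng, n=200, k_need=2, k_nonneed=2, binary_x=False):
    income = rng.uniform(0, 1e4, n)
    w = rng.uniform(0.5, 2.0, n)
    rank = weighted_fractional_rank(income, w)
    k = k_need + k_nonneed
    if binary_x:
        Xs = rng.integers(0, 2, (n, k)).astype(float)
    else:
        Xs = rng.standard_normal((n, k))
    X = np.column_stack([np.ones(n), Xs])
    latent = -0.3 + Xs @ rng.normal(0, 0.4, k) + rng.standard_normal(n)
    y = (latent > 0).astype(float)
    names = ["intercept"] + [f"x{j}" for j in range(k)]
    classes = ["intercept"] + ["need"] * k_need + ["nonneed"] * k_nonneed
    return y, X, names, classes, list(names), w, rank


class TestIdentities:
    def test_ols_perfect_fit_single_regressor(self, rng):
        n = 120
        income = rng.uniform(0, 1e4, n)
        w = rng.uniform(0.5, 2.0, n)
        rank = weighted_fractional_rank(income, w)
        x = (rng.random(n) < 0.4).astype(float)
        X = np.column_stack([np.ones(n), x])
        res = decompose_arrays(x, X, ["intercept", "x"], ["intercept", "need"],
                               ["intercept", "x"], w, rank, model="ols")
        cci_y = erreygers_index(x, rank, w).value
        assert res.contributions[0].contribution == pytest.approx(cci_y, abs=1e-12)
        assert res.residual_term == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("model", ["ols", "probit_approx"])
    def test_adding_up_identity(self, rng, model):
        """CCI = sum of contributions + residual term, exactly."""
        for _ in range(100 if model == "ols" else 20):
            y, X, names, classes, factors, w, rank = random_instance(rng)
            if y.mean() in (0.0, 1.0):
                continue
            res = decompose_arrays(y, X, names, classes, factors, w, rank,
                                   model=model)
            total = sum(c.contribution for c in res.contributions) + res.residual_term
            assert res.cci_total - total == pytest.approx(0.0, abs=1e-10)
            assert res.hi == pytest.approx(res.cci_total - res.need_sum, abs=1e-12)
            assert horizontal_inequity(res) == pytest.approx(res.hi, abs=1e-15)

    def test_no_need_variables_means_hi_equals_cci(self, rng):
        y, X, names, _, factors, w, rank = random_instance(rng)
        classes = ["intercept"] + ["nonneed"] * (X.shape[1] - 1)
        res = decompose_arrays(y, X, names, classes, factors, w, rank, model="ols")
        assert res.hi == pytest.approx(res.cci_total, abs=1e-15)
        assert res.need_sum == 0.0

    def test_rank_orthogonal_regressor_contributes_nothing(self, rng):
        n = 300
        income = rng.uniform(0, 1e4, n)
        w = np.ones(n)
        rank = weighted_fractional_rank(income, w)
        x = rng.standard_normal(n)
        # project out the rank so cov_w(x, rank) == 0 exactly
        r_c = rank - rank.mean()
        x = x - x @ r_c / (r_c @ r_c) * r_c
        z = rng.standard_normal(n)
        y = ((x + z + rng.standard_normal(n)) > 0).astype(float)
        X = np.column_stack([np.ones(n), x, z])
        res = decompose_arrays(y, X, ["intercept", "x", "z"],
                               ["intercept", "need", "nonneed"],
                               ["intercept", "x", "z"], w, rank, model="ols")
        assert res.contributions[0].contribution == pytest.approx(0.0, abs=1e-12)

    def test_factor_rollup_sums_dummy_contributions(self, share_like_prepared):
        gdf = share_like_prepared[share_like_prepared.group == "A"]
        res = decompose(gdf, "y_postponed", group="A")
        rolled = res.by_factor()
        sah_direct = sum(c.contribution for c in res.contributions
                         if c.factor == "sah")
        sah_rolled = rolled.loc[rolled.factor == "sah", "contribution"].iloc[0]
        assert sah_rolled == pytest.approx(sah_direct, abs=1e-15)
        assert rolled.contribution.sum() == pytest.approx(
            res.need_sum + res.nonneed_sum, abs=1e-12)


class TestSimulations:
    def test_null_inequity_recovers_zero_hi(self):
        """delta = 0, gamma = 0: all systematic concentration flows through
        need, so the mean HI over replicates is near zero."""
        his = []
        for s in range(200):
            df = prepare(generate_dataset(
                get_scenario("null_need_only", n_per_group=20_000, seed=50_000 + s)))
            his.append(decompose(df, "y_postponed").hi)
        assert abs(float(np.mean(his))) < 0.01

    def test_negative_income_effect_yields_negative_hi(self):
        """Poor denied more at equal need: HI < 0 in at least 95% of runs."""
        neg = 0
        n_rep = 200
        for s in range(n_rep):
            df = prepare(generate_dataset(
                get_scenario("pro_rich_denial", n_per_group=20_000, seed=90_000 + s)))
            neg += decompose(df, "y_denied").hi < 0
        assert neg >= 0.95 * n_rep

    def test_indirect_standardization_cross_check(self, share_like_prepared):
        """The indirect-standardization HI agrees with the
        subtraction-of-contributions HI up to linearization error."""
        df = prepare(generate_dataset(
            get_scenario("pro_rich_denial", n_per_group=20_000, seed=123)))
        hi_sub = decompose(df, "y_denied").hi
        hi_ind = hi_indirect_standardization(df, "y_denied")
        assert hi_ind == pytest.approx(hi_sub, abs=0.01)
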
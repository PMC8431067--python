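"""Concentration indices: hand-derived values, oracle equivalence, SEs."""

import numpy as np
import pytest
import statsmodels.api as sm

from hequity import (IndexKind, concentration_index, convenient_regression_index,
                     erreygers_index, generalized_ci, index_standard_error,
                     weighted_fractional_rank)
from hequity.errors import (DegenerateOutcomeError, UndefinedIndexError,
                            UndefinedSEError)

RANKS4 = np.array([0.125, 0.375, 0.625, 0.875])
ONES4 = np.ones(4)


def brute_force_ci(y, rank):
    """Independent demeaned-sum oracle: 2 sum y_i (r_i - rbar) / (n ybar)."""
    n = len(y)
    rbar = sum(rank) / n
    ybar = sum(y) / n
    acc = 0.0
    for yi, ri in zip(y, rank):
        acc += yi * (ri - rbar)
    return 2.0 * acc / (n * ybar)


class TestValues:
    def test_pro_poor_extreme(self):
        est = concentration_index([1, 1, 0, 0], RANKS4, ONES4)
        assert est.value == pytest.approx(-0.5, abs=1e-15)
        assert erreygers_index([1, 1, 0, 0], RANKS4, ONES4).value == \
            pytest.approx(-1.0, abs=1e-15)

    def test_pro_rich_extreme(self):
        assert concentration_index([0, 0, 1, 1], RANKS4, ONES4).value == \
            pytest.approx(0.5, abs=1e-15)
        assert erreygers_index([0, 0, 1, 1], RANKS4, ONES4).value == \
            pytest.approx(1.0, abs=1e-15)

    def test_constant_outcome_gives_zero(self):
        assert concentration_index([3.0] * 4, RANKS4, ONES4).value == 0.0

    def test_zero_mean_outcome_undefined(self):
        with pytest.raises(UndefinedIndexError):
            concentration_index([-1, 1, -1, 1], RANKS4, ONES4)

    def test_degenerate_binary_outcome_reported(self):
        with pytest.raises(DegenerateOutcomeError):
            erreygers_index([1, 1, 1, 1], RANKS4, ONES4)
        with pytest.raises(DegenerateOutcomeError):
            erreygers_index([0, 0, 0, 0], RANKS4, ONES4)

    def test_generalized_ci_of_residuals(self):
        assert generalized_ci([-1, -1, 1, 1], RANKS4, ONES4).value == \
            pytest.approx(0.5, abs=1e-15)
        # zero-correlation residuals
        assert generalized_ci([1, -1, -1, 1], RANKS4, ONES4).value == \
            pytest.approx(0.0, abs=1e-15)


class TestIdentities:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            n = rng.integers(3, 51)
            y = rng.uniform(0.1, 5.0, n)
            rank = weighted_fractional_rank(rng.uniform(0, 1e4, n), np.ones(n))
            est = concentration_index(y, rank, np.ones(n))
            assert est.value == pytest.approx(brute_force_ci(y, rank), abs=1e-12)

    def test_erreygers_is_four_mean_times_ci(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 80))
            y = rng.integers(0, 2, n).astype(float)
            if y.mean() in (0.0, 1.0):
                continue
            w = rng.uniform(0.2, 3.0, n)
            rank = weighted_fractional_rank(rng.uniform(0, 1e4, n), w)
            ci = concentration_index(y, rank, w).value
            cci = erreygers_index(y, rank, w).value
            mu = np.average(y, weights=w)
            assert cci == pytest.approx(4.0 * mu * ci, abs=1e-12)
            assert -1.0 - 1e-12 <= cci <= 1.0 + 1e-12
            assert mu - 1 - 1e-12 <= ci <= 1 - mu + 1e-12

    def test_gci_equals_mean_times_ci(self, rng):
        for _ in range(20):
            n = 30
            v = rng.normal(2.0, 1.0, n)
            w = rng.uniform(0.5, 2.0, n)
            rank = weighted_fractional_rank(rng.uniform(0, 1, n), w)
            gci = generalized_ci(v, rank, w).value
            ci = concentration_index(v, rank, w).value
            assert gci == pytest.approx(np.average(v, weights=w) * ci, abs=1e-12)

    def test_scale_invariance_of_standard_ci(self, rng):
        y = rng.uniform(0.5, 2.0, 40)
        w = rng.uniform(0.5, 2.0, 40)
        rank = weighted_fractional_rank(rng.uniform(0, 1, 40), w)
        base = concentration_index(y, rank, w).value
        assert concentration_index(17.3 * y, rank, w).value == \
            pytest.approx(base, rel=1e-12)

    def test_transfer_from_poorest_to_richest_increases_ci(self, rng):
        n = 30
        y = rng.uniform(1.0, 2.0, n)
        income = rng.uniform(0, 1e4, n)
        rank = weighted_fractional_rank(income, np.ones(n))
        poorest, richest = np.argmin(rank), np.argmax(rank)
        y2 = y.copy()
        y2[poorest] -= 0.5
        y2[richest] += 0.5
        assert concentration_index(y2, rank, np.ones(n)).value > \
            concentration_index(y, rank, np.ones(n)).value


class TestStandardErrors:
    def test_convenient_slope_equals_covariance_index(self, rng):
        for _ in range(100):
            n = 20
            y = rng.integers(0, 2, n).astype(float)
            if y.mean() in (0.0, 1.0):
                continue
            w = rng.uniform(0.3, 3.0, n)
            rank = weighted_fractional_rank(rng.uniform(0, 1, n), w)
            for kind, direct in [
                    (IndexKind.standard_CI, concentration_index),
                    (IndexKind.erreygers_CCI, erreygers_index)]:
                conv = convenient_regression_index(y, rank, w, kind)
                assert conv.value == pytest.approx(direct(y, rank, w).value,
                                                   abs=1e-10)

    def test_hc1_matches_statsmodels_with_equal_weights(self, rng):
        n = 150
        y = rng.integers(0, 2, n).astype(float)
        rank = weighted_fractional_rank(rng.uniform(0, 1, n), np.ones(n))
        est = convenient_regression_index(y, rank, np.ones(n),
                                          IndexKind.erreygers_CCI)
        lhs = 8.0 * np.var(rank) * y
        ols = sm.OLS(lhs, sm.add_constant(rank)).fit(cov_type="HC1")
        assert est.value == pytest.approx(ols.params[1], abs=1e-12)
        assert est.se == pytest.approx(ols.bse[1], rel=1e-10)

    def test_weight_rescaling_leaves_value_and_se_unchanged(self, rng):
        n = 60
        y = rng.integers(0, 2, n).astype(float)
        w = rng.uniform(0.5, 2.0, n)
        rank = weighted_fractional_rank(rng.uniform(0, 1, n), w)
        a = erreygers_index(y, rank, w, se=True)
        b = erreygers_index(y, rank, 2.0 * w, se=True)
        assert a.value == pytest.approx(b.value, abs=1e-12)
        assert a.se == pytest.approx(b.se, abs=1e-12)

    def test_constant_outcome_has_zero_slope_finite_se(self):
        rank = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        est = convenient_regression_index(np.full(5, 2.0), rank, np.ones(5),
                                          IndexKind.generalized_GCI)
        assert est.value == pytest.approx(0.0, abs=1e-14)
        assert np.isfinite(est.se)

    def test_zero_rank_variance_is_undefined_se(self):
        with pytest.raises(UndefinedSEError):
            index_standard_error(np.array([0, 1, 0, 1.0]), np.full(4, 0.5),
                                 np.ones(4), IndexKind.erreygers_CCI)
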
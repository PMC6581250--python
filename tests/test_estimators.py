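"""Estimator oracles: hand computations, algebraic identities, diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import statsmodels.api as sm

from mrtri.estimators import (
    heterogeneity,
    ivw,
    leave_one_out,
    mr_egger,
    pool_fixed,
    wald_ratio,
    weighted_median,
    weighted_median_point,
    RatioEstimate,
)
from mrtri.exceptions import (
    CollinearityError,
    DegenerateInstrumentError,
    ValidationError,
)
from mrtri.summary_io import HarmonisedRecord

from conftest import make_harmonised, random_harmonised


def rec(beta_exp, beta_out, se_out, se_exp=1e-3, rsid="rs1"):
    return HarmonisedRecord(rsid=rsid, beta_exp=beta_exp, se_exp=se_exp,
                            beta_out=beta_out, se_out=se_out)


class TestWaldRatio:
    def test_direct_division(self):
        r = wald_ratio(rec(0.5, 2.0, 0.5))
        assert r.ratio == pytest.approx(4.0)
        assert r.se == pytest.approx(1.0)
        assert r.weight == pytest.approx(1.0)

    def test_null_numerator(self):
        r = wald_ratio(rec(0.1, 0.0, 1.0))
        assert r.ratio == 0.0 and r.se == pytest.approx(10.0)

    def test_zero_exposure_effect_errors(self):
        with pytest.raises(DegenerateInstrumentError, match="rs1"):
            wald_ratio(rec(0.0, 1.0, 1.0))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        beta_exp=st.floats(0.001, 10.0), beta_out=st.floats(-5.0, 5.0),
        se_out=st.floats(0.001, 5.0), k=st.floats(0.01, 100.0),
    )
    def test_homogeneity_in_exposure_scale(self, beta_exp, beta_out, se_out, k):
        """Scaling the exposure effect by k scales ratio and SE by 1/k."""
        base = wald_ratio(rec(beta_exp, beta_out, se_out))
        scaled = wald_ratio(rec(beta_exp * k, beta_out, se_out))
        assert scaled.ratio == pytest.approx(base.ratio / k, rel=1e-9)
        assert scaled.se == pytest.approx(base.se / k, rel=1e-9)

    def test_full_delta_exceeds_first_order(self):
        first = wald_ratio(rec(0.5, 2.0, 0.5, se_exp=0.1))
        delta = wald_ratio(rec(0.5, 2.0, 0.5, se_exp=0.1), full_delta=True)
        assert delta.se > first.se
        assert delta.ratio == first.ratio


class TestPoolFixed:
    def test_single_estimate_identity(self):
        e = RatioEstimate("rs1", 3.0, 0.5)
        pooled = pool_fixed([e])
        assert pooled.beta == pytest.approx(3.0)
        assert pooled.se == pytest.approx(0.5)

    def test_hand_computed_example(self):
        """Ratios 4 +/- 1 and 2 +/- 2 pool to 3.6 +/- sqrt(1/1.25)."""
        pooled = pool_fixed([RatioEstimate("a", 4.0, 1.0), RatioEstimate("b", 2.0, 2.0)])
        assert pooled.beta == pytest.approx(3.6)
        assert pooled.se == pytest.approx(1.25 ** -0.5)  # ~0.894

    def test_duplicating_inputs_halves_variance(self):
        est = [RatioEstimate("a", 4.0, 1.0), RatioEstimate("b", 2.0, 2.0)]
        doubled = pool_fixed(est + [RatioEstimate(e.id + "x", e.ratio, e.se) for e in est])
        single = pool_fixed(est)
        assert doubled.beta == pytest.approx(single.beta)
        assert doubled.se ** 2 == pytest.approx(single.se ** 2 / 2)

    def test_order_invariance(self):
        est = [RatioEstimate(f"r{i}", r, s)
               for i, (r, s) in enumerate([(4, 1), (2, 2), (-1, 0.5)])]
        assert pool_fixed(est).beta == pytest.approx(pool_fixed(est[::-1]).beta)

    def test_empty_list_errors(self):
        with pytest.raises(ValidationError):
            pool_fixed([])


class TestIvw:
    def test_hand_computation(self):
        hset = make_harmonised([1.0, 1.0], [4.0, 2.0], [1.0, 2.0])
        assert ivw(hset).beta == pytest.approx(3.6)

    @pytest.mark.parametrize("seed", range(10))
    def test_identity_with_pooled_wald_ratios(self, seed):
        """IVW point estimate equals the pooled Wald ratios to 10+ digits."""
        hset = random_harmonised(np.random.default_rng(seed))
        pooled = pool_fixed([wald_ratio(r) for r in hset.records])
        result = ivw(hset)
        assert result.beta == pytest.approx(pooled.beta, rel=1e-12)
        assert result.se == pytest.approx(pooled.se, rel=1e-12)

    def test_perfect_proportionality(self):
        e = np.array([0.02, 0.05, 0.11])
        hset = make_harmonised(e, 3.0 * e, [0.01, 0.02, 0.03])
        result = ivw(hset)
        assert result.beta == pytest.approx(3.0, rel=1e-12)
        ratios = [wald_ratio(r) for r in hset.records]
        assert heterogeneity(ratios, result).q == pytest.approx(0.0, abs=1e-18)

    def test_needs_two_instruments(self):
        with pytest.raises(ValidationError):
            ivw(make_harmonised([0.1], [0.2], [0.1]))

    def test_t_interval_wider_than_normal(self):
        hset = make_harmonised([1.0, 1.0, 1.0], [4.0, 2.0, 3.0], [1.0, 2.0, 1.0])
        t_res, n_res = ivw(hset, ci="t"), ivw(hset, ci="normal")
        assert t_res.ci_high - t_res.ci_low > n_res.ci_high - n_res.ci_low


class TestEgger:
    def test_exact_linear_fit(self):
        e = np.array([0.02, 0.05, 0.11, 0.2])
        hset = make_harmonised(e, 1.0 + 2.0 * e, [0.01, 0.04, 0.02, 0.03])
        res = mr_egger(hset)
        assert res.intercept.beta == pytest.approx(1.0, rel=1e-10)
        assert res.slope.beta == pytest.approx(2.0, rel=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_constrained_intercept_reproduces_ivw(self, seed):
        """Weighted regression through the origin (the Egger model with its
        intercept constrained to zero) is exactly the IVW estimator."""
        hset = random_harmonised(np.random.default_rng(seed))
        E = np.array([r.beta_exp for r in hset.records])
        y = np.array([r.beta_out for r in hset.records])
        w = np.array([r.se_out ** -2 for r in hset.records])
        constrained = sm.WLS(y, E[:, None], weights=w).fit()
        assert ivw(hset).beta == pytest.approx(float(constrained.params[0]), rel=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels_wls(self, seed):
        """Point estimates agree with an independent WLS fit with intercept."""
        hset = random_harmonised(np.random.default_rng(100 + seed))
        E = np.array([r.beta_exp for r in hset.records])
        y = np.array([r.beta_out for r in hset.records])
        w = np.array([r.se_out ** -2 for r in hset.records])
        fit = sm.WLS(y, sm.add_constant(E), weights=w).fit()
        res = mr_egger(hset)
        assert res.intercept.beta == pytest.approx(float(fit.params[0]), rel=1e-9)
        assert res.slope.beta == pytest.approx(float(fit.params[1]), rel=1e-9)

    def test_affine_equivariance(self):
        rng = np.random.default_rng(7)
        hset = random_harmonised(rng)
        shifted = make_harmonised(
            [r.beta_exp for r in hset.records],
            [r.beta_out + 0.25 for r in hset.records],
            [r.se_out for r in hset.records],
        )
        base, moved = mr_egger(hset), mr_egger(shifted)
        assert moved.intercept.beta == pytest.approx(base.intercept.beta + 0.25, rel=1e-9)
        assert moved.slope.beta == pytest.approx(base.slope.beta, rel=1e-9, abs=1e-12)

    def test_collinear_exposure_effects_error(self):
        with pytest.raises(CollinearityError):
            mr_egger(make_harmonised([0.1, 0.1, 0.1], [1, 2, 3], [1, 1, 1]))

    def test_needs_three_instruments(self):
        with pytest.raises(ValidationError):
            mr_egger(make_harmonised([0.1, 0.2], [1, 2], [1, 1]))


class TestWeightedMedian:
    def test_equal_weights_is_simple_median(self):
        hset = make_harmonised([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        assert weighted_median(hset, n_boot=10, seed=0).beta == pytest.approx(2.0)

    def test_hand_interpolation(self):
        """Ratios {1,2,3}, weights {0.1,0.2,0.7}: percentiles {5,20,65},
        the 50th percentile interpolates to 2 + 30/45."""
        point, clamped = weighted_median_point(
            np.array([1.0, 2.0, 3.0]), np.array([0.1, 0.2, 0.7])
        )
        assert point == pytest.approx(2.0 + 30.0 / 45.0)
        assert not clamped

    def test_dominant_weight_stays_interpolated(self):
        """With normalised weights the 50th percentile always lies within
        [p_1, p_J] (p_1 = 100 w_1/2 <= 50 <= p_J), so even a near-unit weight
        interpolates rather than clamps: 1 + (50-49)/(98.5-49)."""
        point, clamped = weighted_median_point(
            np.array([1.0, 2.0, 3.0]), np.array([0.98, 0.01, 0.01])
        )
        assert point == pytest.approx(1.0 + 1.0 / 49.5)
        assert not clamped

    def test_bootstrap_determinism_and_stability(self):
        hset = make_harmonised(
            [0.05, 0.1, 0.2, 0.07], [0.01, 0.03, 0.05, 0.02],
            [0.01, 0.02, 0.02, 0.015],
        )
        a = weighted_median(hset, n_boot=1000, seed=42)
        b = weighted_median(hset, n_boot=1000, seed=42)
        assert a.se == b.se  # bit-identical under the same seed
        c = weighted_median(hset, n_boot=1000, seed=43)
        # different seeds agree within a few bootstrap SDs of the SE itself
        assert abs(c.se - a.se) / a.se < 3 * (2 / 1000) ** 0.5

    def test_nboot_guard(self):
        hset = make_harmonised([1, 1, 1], [1, 2, 3], [1, 1, 1])
        with pytest.raises(ValidationError):
            weighted_median(hset, n_boot=1, seed=0)


class TestHeterogeneity:
    def test_identical_ratios_no_dispersion(self):
        est = [RatioEstimate(f"r{i}", 2.0, 1.0) for i in range(4)]
        h = heterogeneity(est, pool_fixed(est))
        assert h.q == pytest.approx(0.0) and h.i2 == 0.0

    def test_hand_computed_q(self):
        """Ratios 4 +/- 1, 2 +/- 2: Q = 0.8 < df = 1, so I2 floors at 0."""
        est = [RatioEstimate("a", 4.0, 1.0), RatioEstimate("b", 2.0, 2.0)]
        h = heterogeneity(est, pool_fixed(est))
        assert h.q == pytest.approx(0.8)
        assert h.df == 1
        assert h.i2 == 0.0

    def test_contributions_sum_to_q(self):
        rng = np.random.default_rng(3)
        est = [RatioEstimate(f"r{i}", rng.normal(), rng.uniform(0.5, 2)) for i in range(6)]
        h = heterogeneity(est, pool_fixed(est))
        assert sum(c for _, c in h.per_unit) == pytest.approx(h.q)

    def test_monotone_in_outlier_deviation(self):
        qs = []
        for outlier in (3.0, 5.0, 9.0):
            est = [RatioEstimate("a", 2.0, 1.0), RatioEstimate("b", 2.0, 1.0),
                   RatioEstimate("c", outlier, 1.0)]
            qs.append(heterogeneity(est, pool_fixed(est)).q)
        assert qs[0] < qs[1] < qs[2]

    def test_single_estimate_degenerate(self):
        est = [RatioEstimate("a", 2.0, 1.0)]
        h = heterogeneity(est, pool_fixed(est))
        assert h.q == 0.0 and h.i2 == 0.0 and h.degenerate


class TestLeaveOneOut:
    def test_exchangeable_instruments(self):
        hset = make_harmonised([0.1] * 4, [0.05] * 4, [0.01] * 4)
        loo = leave_one_out(hset, "ivw")
        for row in loo.rows:
            assert row.result.beta == pytest.approx(loo.baseline.beta)

    def test_outlier_exclusion_is_extreme(self):
        hset = make_harmonised(
            [0.1, 0.1, 0.1, 0.1, 0.1],
            [0.05, 0.052, 0.048, 0.05, 0.30],  # planted outlier last
            [0.01] * 5,
        )
        loo = leave_one_out(hset, "ivw")
        betas = {row.excluded_id: row.result.beta for row in loo.rows}
        assert min(betas, key=betas.get) == "rs4"
        assert len(loo.rows) == 5

    def test_infeasible_rows_flagged(self):
        hset = make_harmonised([0.1, 0.2, 0.3], [0.01, 0.02, 0.03], [0.01] * 3)
        loo = leave_one_out(hset, "egger-slope")
        assert all(row.result is None and row.infeasible_reason for row in loo.rows)
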
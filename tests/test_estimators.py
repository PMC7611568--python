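import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsmr.datatypes import EstimationError, RatioEstimate
from tsmr.estimators import (
    cochran_q,
    ivw,
    leave_one_out_ivw,
    mr_egger,
    wald_ratio,
    wald_ratios,
    weighted_median,
)


class TestWaldRatio:
    def test_first_order_formula(self, make_instrument):
        r = wald_ratio(make_instrument(bx=0.1, sx=0.01, by=0.05, sy=0.02))
        assert r.theta == pytest.approx(0.5)
        assert r.sigma == pytest.approx(0.2)

    def test_zero_outcome_effect(self, make_instrument):
        r = wald_ratio(make_instrument(bx=0.1, sx=0.01, by=0.0, sy=0.02))
        assert r.theta == 0.0
        assert r.sigma == pytest.approx(0.2)

    def test_second_order_adds_exposure_uncertainty(self, make_instrument):
        instr = make_instrument(bx=0.2, sx=0.02, by=0.03, sy=0.01)
        r = wald_ratio(instr, se_order="second")
        expected = math.sqrt(0.01**2 / 0.04 + 0.03**2 * 0.0004 / 0.0016)
        assert r.sigma == pytest.approx(expected)
        # the second-order SE always dominates the first-order one
        assert r.sigma > wald_ratio(instr).sigma

    def test_degenerate_instrument_rejected(self):
        from tsmr.datatypes import HarmonizedInstrument

        with pytest.raises(Exception):
            # beta_exposure = 0 cannot even be constructed post-harmonization
            HarmonizedInstrument("rs1", 0.0, 0.01, 0.05, 0.02)


class TestIVW:
    def test_single_ratio_is_identity_under_both_models(self):
        single = [RatioEstimate("rs1", 0.5, 0.2)]
        for model in ("fixed", "multiplicative_random"):
            res = ivw(single, model=model)
            assert res.estimate == pytest.approx(0.5)
            assert res.se == pytest.approx(0.2)
            assert math.isnan(res.q_stat)

    def test_worked_instance_matches_hand_arithmetic(self, worked_ratios):
        res = ivw(worked_ratios, model="fixed")
        assert res.estimate == pytest.approx(0.15714, abs=1e-5)
        assert res.se == pytest.approx(0.04364, abs=1e-5)
        assert res.q_stat == pytest.approx(0.28571, abs=1e-5)
        assert res.i_squared == 0.0

    def test_empty_input_is_an_error(self):
        with pytest.raises(EstimationError):
            ivw([])

    def test_fixed_ivw_equals_zero_intercept_wls(self, make_instrument):
        """IVW on first-order ratios == weighted no-intercept regression of
        b_Y on b_X with weights 1/s_Y² (independent statsmodels fit)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(42)
        for _ in range(10):
            n = rng.integers(3, 20)
            instruments = [
                make_instrument(
                    f"rs{i}",
                    bx=rng.uniform(0.02, 0.2),
                    sx=rng.uniform(0.001, 0.01),
                    by=rng.normal(0, 0.05),
                    sy=rng.uniform(0.005, 0.05),
                )
                for i in range(n)
            ]
            res = ivw(wald_ratios(instruments), model="fixed")
            bx = np.array([i.beta_exposure for i in instruments])
            by = np.array([i.beta_outcome for i in instruments])
            w = np.array([i.se_outcome for i in instruments]) ** -2.0
            fit = sm.WLS(by, bx, weights=w).fit()
            assert res.estimate == pytest.approx(fit.params[0], rel=1e-10)

    def test_mre_se_never_below_fixed_se(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ratios = [
                RatioEstimate(f"rs{i}", rng.normal(0, 0.3), rng.uniform(0.01, 0.3))
                for i in range(int(rng.integers(2, 15)))
            ]
            fixed = ivw(ratios, "fixed")
            mre = ivw(ratios, "multiplicative_random")
            assert mre.se >= fixed.se - 1e-15
            assert mre.estimate == pytest.approx(fixed.estimate)
            # equality exactly when Q <= J-1
            if fixed.q_stat <= len(ratios) - 1:
                assert mre.se == pytest.approx(fixed.se)
            else:
                assert mre.se > fixed.se

    def test_null_simulation_is_unbiased(self):
        """Ratio-level Monte-Carlo: true effect 0, J=60, mean estimate
        within twice its Monte-Carlo SE of zero."""
        rng = np.random.default_rng(0)
        estimates = []
        for _ in range(2000):
            sigma = rng.uniform(0.05, 0.3, 60)
            theta = rng.normal(0.0, sigma)
            ratios = [
                RatioEstimate(f"rs{i}", float(t), float(s))
                for i, (t, s) in enumerate(zip(theta, sigma))
            ]
            estimates.append(ivw(ratios, "fixed").estimate)
        estimates = np.asarray(estimates)
        mc_se = estimates.std(ddof=1) / math.sqrt(len(estimates))
        assert abs(estimates.mean()) < 2 * mc_se


class TestWeightedMedian:
    def test_degenerate_equal_ratios(self):
        ratios = [RatioEstimate(f"rs{i}", 0.3, 0.1) for i in range(5)]
        res = weighted_median(ratios, n_boot=200, seed=0)
        assert res.estimate == pytest.approx(0.3)

    def test_worked_interpolation(self, worked_ratios):
        res = weighted_median(worked_ratios, n_boot=200, seed=0)
        assert res.estimate == pytest.approx(0.1575, abs=1e-6)

    def test_requires_three_ratios(self):
        with pytest.raises(EstimationError):
            weighted_median(
                [RatioEstimate("a", 0.1, 0.1), RatioEstimate("b", 0.2, 0.1)],
                n_boot=200,
                seed=0,
            )

    def test_estimate_within_ratio_range(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            ratios = [
                RatioEstimate(f"rs{i}", rng.normal(0, 1), rng.uniform(0.01, 1))
                for i in range(int(rng.integers(3, 25)))
            ]
            est = weighted_median(ratios, n_boot=100, seed=1).estimate
            thetas = [r.theta for r in ratios]
            assert min(thetas) <= est <= max(thetas)

    def test_robust_when_valid_instruments_hold_majority_weight(self):
        """30 valid ratios at 0.1 and 30 shifted by +0.5; valid weight > 50%
        keeps the median at the valid value as noise vanishes."""
        valid = [RatioEstimate(f"v{i:02d}", 0.1, 0.01) for i in range(30)]
        invalid = [RatioEstimate(f"x{i:02d}", 0.6, 0.012) for i in range(30)]
        w_valid = sum(r.weight for r in valid)
        w_total = w_valid + sum(r.weight for r in invalid)
        assert w_valid / w_total > 0.5
        res = weighted_median(valid + invalid, n_boot=200, seed=0)
        assert res.estimate == pytest.approx(0.1, abs=0.02)

    def test_bootstrap_reproducible_given_seed(self, worked_ratios):
        a = weighted_median(worked_ratios, n_boot=300, seed=9)
        b = weighted_median(worked_ratios, n_boot=300, seed=9)
        assert a.se == b.se


class TestMrEgger:
    def test_exact_linear_fit(self, make_instrument):
        rng = np.random.default_rng(1)
        instruments = [
            make_instrument(
                f"rs{i}",
                bx=bx,
                sx=0.01,
                by=0.01 + 0.5 * bx,
                sy=float(rng.uniform(0.01, 0.05)),
            )
            for i, bx in enumerate(np.linspace(0.05, 0.3, 8))
        ]
        slope, intercept = mr_egger(instruments)
        assert slope.estimate == pytest.approx(0.5, abs=1e-10)
        assert intercept.estimate == pytest.approx(0.01, abs=1e-12)
        assert slope.q_stat == pytest.approx(0.0, abs=1e-18)

    def test_matches_statsmodels_wls_point_estimates(self, make_instrument):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        instruments = [
            make_instrument(
                f"rs{i}",
                bx=rng.uniform(0.02, 0.3),
                sx=0.005,
                by=rng.normal(0.01, 0.05),
                sy=rng.uniform(0.01, 0.05),
            )
            for i in range(12)
        ]
        slope, intercept = mr_egger(instruments)
        bx = np.array([i.beta_exposure for i in instruments])
        by = np.array([i.beta_outcome for i in instruments])
        w = np.array([i.se_outcome for i in instruments]) ** -2.0
        fit = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
        assert intercept.estimate == pytest.approx(fit.params[0], rel=1e-9)
        assert slope.estimate == pytest.approx(fit.params[1], rel=1e-9)
        # statsmodels scales by the residual variance with no floor; when the
        # fit is overdispersed (scale > 1) the SEs agree exactly
        if fit.scale > 1:
            assert slope.se == pytest.approx(fit.bse[1], rel=1e-9)

    def test_collinear_exposure_effects_rejected(self, make_instrument):
        instruments = [
            make_instrument(f"rs{i}", bx=0.1, by=0.05) for i in range(4)
        ]
        with pytest.raises(EstimationError, match="variation"):
            mr_egger(instruments)

    def test_balanced_pleiotropy_gives_null_intercept(self, make_instrument):
        """Simulation oracle: alpha ~ N(0, 0.01), theta = 0.1; the mean
        intercept over replicates stays within 2 MC-SEs of zero."""
        rng = np.random.default_rng(12)
        intercepts = []
        for _ in range(500):
            gamma = np.abs(rng.normal(0, 0.03, 60)) + 0.01
            sy = rng.uniform(0.01, 0.02, 60)
            by = rng.normal(0.1 * gamma + rng.normal(0, 0.01, 60), sy)
            instruments = [
                make_instrument(f"rs{i:02d}", bx=g, sx=1e-6, by=b, sy=s)
                for i, (g, b, s) in enumerate(zip(gamma, by, sy))
            ]
            intercepts.append(mr_egger(instruments)[1].estimate)
        intercepts = np.asarray(intercepts)
        mc_se = intercepts.std(ddof=1) / math.sqrt(len(intercepts))
        assert abs(intercepts.mean()) < 2 * mc_se


class TestCochranQ:
    def test_identical_ratios_no_heterogeneity(self):
        ratios = [RatioEstimate(f"rs{i}", 0.2, 0.1) for i in range(4)]
        q, df, p, i2 = cochran_q(ratios)
        assert q == pytest.approx(0.0, abs=1e-25)
        assert df == 3
        assert p == pytest.approx(1.0)
        assert i2 == 0.0

    def test_worked_instance(self, worked_ratios):
        q, df, p, i2 = cochran_q(worked_ratios)
        assert q == pytest.approx(0.28571, abs=1e-5)
        assert df == 2

    def test_two_distant_ratios(self):
        # mean 0.5; Q = 100*0.25 + 100*0.25 = 50
        ratios = [RatioEstimate("a", 0.0, 0.1), RatioEstimate("b", 1.0, 0.1)]
        q, df, p, i2 = cochran_q(ratios)
        assert q == pytest.approx(50.0)
        assert df == 1
        assert i2 == pytest.approx((50 - 1) / 50 * 100)

    def test_single_ratio_rejected(self):
        with pytest.raises(EstimationError):
            cochran_q([RatioEstimate("a", 0.1, 0.1)])


@given(
    data=st.lists(
        st.tuples(
            st.floats(-1, 1),
            st.floats(0.01, 1),
            st.floats(0.02, 0.3),
            st.floats(0.001, 0.01),
        ),
        min_size=3,
        max_size=15,
    ),
    seed=st.integers(0, 2**16),
)
@settings(max_examples=50, deadline=None)
def test_estimators_invariant_to_input_order(data, seed):
    """Shuffling the instruments never changes any estimate."""
    from tsmr.datatypes import HarmonizedInstrument

    instruments = [
        HarmonizedInstrument(f"rs{i:03d}", bx, sx, by, sy)
        for i, (by, sy, bx, sx) in enumerate(data)
    ]
    rng = np.random.default_rng(seed)
    shuffled = list(instruments)
    rng.shuffle(shuffled)

    r1, r2 = wald_ratios(instruments), wald_ratios(shuffled)
    assert ivw(r1, "fixed").estimate == pytest.approx(
        ivw(r2, "fixed").estimate, rel=1e-12
    )
    assert weighted_median(r1, 100, seed=0).estimate == pytest.approx(
        weighted_median(r2, 100, seed=0).estimate, rel=1e-12
    )
    try:
        s1, i1 = mr_egger(instruments)
        s2, i2 = mr_egger(shuffled)
        assert s1.estimate == pytest.approx(s2.estimate, rel=1e-9)
        assert i1.estimate == pytest.approx(i2.estimate, rel=1e-9, abs=1e-12)
    except EstimationError:
        pass  # collinear b_X draws are legitimately rejected


def test_leave_one_out_matches_refit(worked_ratios):
    loo = leave_one_out_ivw(worked_ratios)
    for rid in ("rs_a", "rs_b", "rs_c"):
        rest = [r for r in worked_ratios if r.variant_id != rid]
        assert loo[rid] == pytest.approx(ivw(rest, "fixed").estimate)
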
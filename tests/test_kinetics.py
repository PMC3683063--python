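"""Monod rate law, crossover/classification, doubling times, and Monod fitting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

from shulk.kinetics import (
    GrowthCurve,
    MonodFitError,
    MonodParams,
    NoExponentialPhaseError,
    RateConcentrationDesign,
    classify_pair,
    crossover_concentration,
    fit_monod,
    generation_time,
    generation_time_replicates,
    monod_rate,
)
from shulk.synth import gen_growth_curves, gen_rate_design

params_st = st.builds(
    MonodParams,
    mu_max=st.floats(0.05, 5.0),
    K_s=st.floats(0.01, 20.0),
)


class TestMonodRate:
    @pytest.mark.parametrize(
        "s, mu_max, K_s, expected",
        [
            (0.0, 1.3, 0.7, 0.0),  # no resource, no growth
            (0.7, 1.3, 0.7, 0.65),  # half-saturation by definition
            (1.6667, 1.0, 1.0, 0.625),  # direct evaluation
        ],
    )
    def test_values(self, s, mu_max, K_s, expected):
        assert monod_rate(s, MonodParams(mu_max, K_s)) == pytest.approx(
            expected, abs=1e-4)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            monod_rate(-0.1, MonodParams(1.0, 1.0))

    @given(params_st)
    def test_monotone_and_bounded(self, p):
        s = np.logspace(-6, 6, 200)
        mu = monod_rate(s, p)
        assert np.all(np.diff(mu) >= 0)
        assert mu.max() <= p.mu_max
        # saturates towards mu_max
        assert mu[-1] == pytest.approx(p.mu_max, rel=1e-4)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MonodParams(mu_max=0.0, K_s=1.0)
        with pytest.raises(ValueError):
            MonodParams(mu_max=1.0, K_s=-1.0)


class TestCrossover:
    def test_worked_pair_matches_bisection_oracle(self, shulk_pair):
        a, b = shulk_pair
        s_star = crossover_concentration(a, b)
        assert s_star == pytest.approx(1.6667, abs=1e-3)
        diff = lambda s: monod_rate(s, a) - monod_rate(s, b)  # noqa: E731
        oracle = brentq(diff, 1e-6, 1e3, xtol=1e-12, rtol=1e-15)
        assert s_star == pytest.approx(oracle, rel=1e-8)

    def test_identical_curves_have_no_crossover(self):
        p = MonodParams(0.9, 0.4)
        assert crossover_concentration(p, p) is None

    def test_dominant_strain_has_no_crossover(self):
        a = MonodParams(1.0, 0.2)  # faster AND thriftier
        b = MonodParams(0.7, 1.0)
        assert crossover_concentration(a, b) is None
        s = np.logspace(-4, 3, 100)
        assert np.all(monod_rate(s, a) - monod_rate(s, b) > 0)

    @given(params_st, params_st)
    def test_classification_consistent_with_crossover(self, a, b):
        label = classify_pair(a, b)
        s_star = crossover_concentration(a, b)
        if label.startswith("sHULK"):
            assert s_star is not None and s_star > 0
            lo = monod_rate(s_star / 2, a) - monod_rate(s_star / 2, b)
            hi = monod_rate(2 * s_star, a) - monod_rate(2 * s_star, b)
            assert lo * hi < 0  # rate difference flips sign across s*
            exploiter_is_a = label == "sHULK_a_exploiter"
            assert (a.mu_max > b.mu_max) == exploiter_is_a
        else:
            assert s_star is None
            if label == "a_dominates":
                s = np.logspace(-4, 3, 50)
                assert np.all(monod_rate(s, a) >= monod_rate(s, b))


class TestClassifyPair:
    def test_examples(self, shulk_pair):
        a, b = shulk_pair
        assert classify_pair(a, b) == "sHULK_a_exploiter"
        assert classify_pair(b, a) == "sHULK_b_exploiter"
        assert classify_pair(MonodParams(1.0, 0.2),
                             MonodParams(0.7, 1.0)) == "a_dominates"
        assert classify_pair(a, a) == "identical"


class TestGenerationTime:
    def test_noiseless_exponential_recovers_doubling_time(self):
        t = np.arange(0, 8.0001, 1 / 6)
        od = 0.05 * 2 ** (t * 60.0 / 50.0)
        res = generation_time(GrowthCurve(times=t, od=od))
        assert res.doubling_min == pytest.approx(50.0, rel=0.02)
        assert res.r_squared > 0.999

    def test_flat_curve_has_no_exponential_phase(self):
        t = np.arange(0, 8.0001, 1 / 6)
        with pytest.raises(NoExponentialPhaseError):
            generation_time(GrowthCurve(times=t, od=np.full_like(t, 0.05)))

    def test_triplicate_recovery_with_noise(self):
        cs = gen_growth_curves(doubling_min=56.5, noise_sd=0.01, seed=7)
        mean, se, results = generation_time_replicates(cs.curves)
        assert mean == pytest.approx(56.5, rel=0.02)
        assert len(results) == 3 and se >= 0

    def test_invariance_to_scaling_and_background(self):
        t = np.arange(0, 8.0001, 1 / 6)
        od = 0.05 * 2 ** (t * 60.0 / 50.0)
        base = generation_time(GrowthCurve(times=t, od=od)).doubling_min
        scaled = generation_time(GrowthCurve(times=t, od=3.7 * od)).doubling_min
        shifted = generation_time(GrowthCurve(times=t, od=od + 0.11)).doubling_min
        assert scaled == pytest.approx(base, rel=1e-9)
        assert shifted == pytest.approx(base, rel=1e-9)

    def test_curve_invariants_enforced(self):
        with pytest.raises(ValueError):
            GrowthCurve(times=np.array([0, 1, 2, 3]), od=np.ones(4))  # < 5 pts
        with pytest.raises(ValueError):
            GrowthCurve(times=np.array([0, 2, 1, 3, 4.0]), od=np.ones(5))


class TestFitMonod:
    def test_noiseless_exact_recovery(self):
        design, _ = gen_rate_design(MonodParams(0.85, 0.15), noise_sd=0.0)
        fit = fit_monod(design)
        assert fit.params.mu_max == pytest.approx(0.85, rel=1e-6)
        assert fit.params.K_s == pytest.approx(0.15, rel=1e-6)
        assert fit.rss < 1e-12
        assert fit.ks_identifiable

    def test_noisy_recovery_within_ten_percent(self):
        design, _ = gen_rate_design(MonodParams(0.85, 0.15), noise_sd=0.01,
                                    seed=3)
        fit = fit_monod(design)
        assert fit.params.mu_max == pytest.approx(0.85, rel=0.10)
        assert fit.params.K_s == pytest.approx(0.15, rel=0.10)
        assert fit.se_mu_max > 0 and fit.se_K_s > 0

    def test_saturated_design_flags_ks(self):
        design = RateConcentrationDesign(
            concentrations=np.array([10.0, 20.0, 40.0, 80.0]),
            rates=np.full(4, 0.85),
        )
        fit = fit_monod(design)
        assert not fit.ks_identifiable

    def test_too_few_concentrations_rejected(self):
        design = RateConcentrationDesign(
            concentrations=np.array([0.1, 0.2, 0.1, 0.2]),
            rates=np.array([0.3, 0.4, 0.31, 0.41]),
        )
        with pytest.raises(ValueError, match="4 distinct"):
            fit_monod(design)
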
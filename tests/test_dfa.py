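"""DFA engine: profile, windowed fluctuation, scaling fit, anchors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eventdfa import (
    DFA,
    DFAConfig,
    FluctuationCurve,
    dfa,
    fit_scaling_index,
    fluctuation_curve,
    integrate_profile,
    window_fluctuation,
)
from eventdfa.exceptions import (
    FitError,
    InsufficientDataError,
    ParameterError,
    WindowError,
)


class TestIntegrateProfile:
    def test_constant_signal_zero_profile(self):
        np.testing.assert_allclose(integrate_profile([1, 1, 1, 1]), [0, 0, 0, 0])

    def test_zero_mean_alternation(self):
        np.testing.assert_allclose(
            integrate_profile([1, -1, 1, -1]), [1, 0, 1, 0]
        )

    def test_random_walk_variance_grows_linearly(self):
        # the profile of fair +/-1 coin flips is a simple random walk;
        # mean subtraction pins the endpoint, so the profile is a bridge:
        # var(S_k) = k (n - k) / n (binomial bridge oracle)
        rng = np.random.default_rng(0)
        n, k = 1000, 200
        ends = [
            integrate_profile(rng.choice([-1, 1], size=n))[k] for _ in range(800)
        ]
        assert np.var(ends) == pytest.approx(k * (n - k) / n, rel=0.15)

    def test_too_short_rejected(self):
        with pytest.raises(InsufficientDataError):
            integrate_profile([1.0, 2.0])


class TestWindowFluctuation:
    def test_affine_profile_annihilated(self):
        profile = 3.0 + 0.7 * np.arange(64)
        for w in (4, 8, 16):
            assert window_fluctuation(profile, w) == pytest.approx(0.0, abs=1e-10)

    def test_matches_bruteforce_on_small_profile(self, naive_F):
        profile = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0])
        assert window_fluctuation(profile, 3) == pytest.approx(
            naive_F(profile, 3), rel=1e-12
        )

    def test_matches_bruteforce_on_random_profiles(self, naive_F):
        rng = np.random.default_rng(1)
        for n in (64, 257, 512):
            profile = np.cumsum(rng.standard_normal(n))
            for w in (4, 8, 16):
                assert window_fluctuation(profile, w) == pytest.approx(
                    naive_F(profile, w), rel=1e-9
                )

    def test_oversized_window_rejected(self):
        with pytest.raises(WindowError):
            window_fluctuation(np.arange(10.0), 6)

    @given(st.floats(min_value=0.1, max_value=100.0))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(7)
        profile = np.cumsum(rng.standard_normal(256))
        f1 = window_fluctuation(profile, 8)
        f2 = window_fluctuation(c * profile, 8)
        assert f2 == pytest.approx(c * f1, rel=1e-9)


class TestFluctuationCurve:
    def test_window_sizes_strictly_increasing_unique(self):
        rng = np.random.default_rng(2)
        curve = fluctuation_curve(
            np.cumsum(rng.standard_normal(2000)), DFAConfig()
        )
        assert np.all(np.diff(curve.window_sizes) > 0)

    def test_monotone_for_random_walk_profile(self):
        rng = np.random.default_rng(3)
        profile = np.cumsum(rng.standard_normal(20_000))
        curve = fluctuation_curve(profile, DFAConfig())
        assert np.all(np.diff(curve.F_values) > 0)

    def test_roundtrip_csv(self, tmp_path):
        curve = FluctuationCurve(np.array([4, 8, 16]), np.array([1.0, 2.0, 4.0]))
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        back = FluctuationCurve.from_csv(path)
        np.testing.assert_array_equal(back.window_sizes, curve.window_sizes)
        np.testing.assert_allclose(back.F_values, curve.F_values)

    def test_infeasible_grid_rejected(self):
        with pytest.raises(InsufficientDataError):
            fluctuation_curve(np.arange(20.0), DFAConfig(min_window=16))


class TestScalingFit:
    def test_exact_power_law(self):
        w = np.array([4, 8, 16, 32])
        curve = FluctuationCurve(w, 2.0 * w.astype(float) ** 0.8)
        alpha, intercept, r2 = fit_scaling_index(curve)
        assert alpha == pytest.approx(0.8, abs=1e-12)
        assert 10**intercept == pytest.approx(2.0, rel=1e-10)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_two_points_slope_one(self):
        curve = FluctuationCurve(np.array([10, 100]), np.array([1.0, 10.0]))
        alpha, _, _ = fit_scaling_index(curve)
        assert alpha == pytest.approx(1.0, abs=1e-12)

    def test_zero_F_in_range_is_fit_error(self):
        curve = FluctuationCurve(np.array([4, 8]), np.array([0.0, 1.0]))
        with pytest.raises(FitError):
            fit_scaling_index(curve)

    def test_fit_range_restriction(self):
        w = np.array([4, 8, 16, 32, 64])
        F = np.where(w < 16, w**1.5, w**0.5).astype(float)
        alpha, _, _ = fit_scaling_index(FluctuationCurve(w, F), (16, 64))
        assert alpha == pytest.approx(0.5, abs=0.01)


class TestEndToEnd:
    def test_white_noise_alpha_half(self):
        alphas = [
            dfa(np.random.default_rng(s).standard_normal(100_000)).alpha
            for s in range(20)
        ]
        assert np.mean(alphas) == pytest.approx(0.5, abs=0.03)

    def test_random_walk_alpha_three_halves(self):
        alphas = [
            dfa(np.cumsum(np.random.default_rng(s).standard_normal(100_000))).alpha
            for s in range(20)
        ]
        assert np.mean(alphas) == pytest.approx(1.5, abs=0.05)

    def test_deterministic_under_fixed_input(self):
        x = np.random.default_rng(5).standard_normal(5000)
        r1, r2 = dfa(x), dfa(x)
        assert r1.alpha == r2.alpha
        np.testing.assert_array_equal(r1.curve.F_values, r2.curve.F_values)

    def test_model_object_facade(self):
        x = np.random.default_rng(6).standard_normal(5000)
        res = DFA(x).fit()
        assert res.alpha == dfa(x).alpha
        assert "scaling index alpha" in res.summary()


class TestConfigValidation:
    def test_min_window_needs_residual_dof(self):
        with pytest.raises(ParameterError):
            DFAConfig(min_window=2)

    def test_needs_two_windows(self):
        with pytest.raises(ParameterError):
            DFAConfig(n_windows=1)
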
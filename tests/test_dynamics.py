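"""Jump-decay impairment process: closed forms, sampling laws, oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asthmasim.dynamics import (
    PhysiologyParams,
    StimulusEvent,
    apply_stimulus,
    decay,
    evaluate_trajectory,
    recovery_crossing_time,
    sample_effect_size,
    sample_stimuli,
    simulate_fixed_step,
    simulate_trajectory,
    trajectory_time_average,
)


class TestDecay:
    @pytest.mark.parametrize(
        "I0,g,dt,expected",
        [
            (5.0, 0.2, 0.0, 5.0),
            (0.0, 0.2, 7.0, 0.0),
            (2.0, 0.1, 10.0, 2.0 * np.exp(-1.0)),  # 0.735759...
        ],
    )
    def test_closed_form(self, I0, g, dt, expected):
        assert decay(I0, g, dt) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("bad", [(-1.0, 0.2, 1.0), (1.0, 0.2, -1.0)])
    def test_invalid_arguments(self, bad):
        with pytest.raises(ValueError):
            decay(*bad)

    @given(
        I0=st.floats(0, 1e3),
        g=st.floats(0, 5),
        dt=st.floats(0, 100),
    )
    @settings(max_examples=200, derandomize=True)
    def test_bounded_and_monotone(self, I0, g, dt):
        out = decay(I0, g, dt)
        assert 0.0 <= out <= I0


class TestStimulus:
    def test_jump_from_rest(self):
        assert apply_stimulus(0.0, 1.5) == 1.5

    def test_additivity(self):
        assert apply_stimulus(2.0, 0.5) == 2.5

    def test_compose_decay_and_jump(self):
        g, delta = 0.3, 4.0
        out = apply_stimulus(decay(apply_stimulus(0.0, 1.0), g, delta), 1.0)
        assert out == pytest.approx(1.0 + np.exp(-g * delta), rel=1e-12)

    def test_nonpositive_jump_rejected(self):
        with pytest.raises(ValueError):
            apply_stimulus(1.0, 0.0)
        with pytest.raises(ValueError):
            StimulusEvent(s=1.0, alpha=-0.1)


class TestPoissonStimuli:
    def test_zero_rate_empty(self):
        assert len(sample_stimuli(0.0, 365, np.random.default_rng(0))) == 0

    def test_count_mean_and_dispersion(self):
        # Poisson(lam*T): mean 36.5, variance/mean 1
        rng = np.random.default_rng(1234)
        counts = np.array(
            [len(sample_stimuli(0.1, 365, rng)) for _ in range(10_000)]
        )
        assert counts.mean() == pytest.approx(36.5, abs=0.6)  # 3 SE
        assert counts.var() / counts.mean() == pytest.approx(1.0, abs=0.05)

    def test_sorted_within_horizon(self):
        t = sample_stimuli(1.0, 50, np.random.default_rng(7))
        assert np.all(np.diff(t) >= 0)
        assert t.min() > 0 and t.max() <= 50


class TestEffectSizes:
    def test_exponential_mean(self):
        rng = np.random.default_rng(5)
        x = sample_effect_size(1.0, 1.0, rng, size=10_000)
        assert x.mean() == pytest.approx(1.0, abs=0.03)  # 3 SE

    def test_sensitivity_scaling(self):
        rng = np.random.default_rng(5)
        x = sample_effect_size(1.0, 0.5, rng, size=10_000)
        assert x.mean() == pytest.approx(0.5, abs=0.015)

    def test_strictly_positive_support(self):
        x = sample_effect_size(0.2, 1.0, np.random.default_rng(9), size=5000)
        assert (x > 0).all()

    def test_invalid_mean(self):
        with pytest.raises(ValueError):
            sample_effect_size(0.0, 1.0, np.random.default_rng(0))


class TestRecoveryCrossing:
    def test_at_threshold_none(self):
        assert recovery_crossing_time(1.0, 0.5, 1.0) is None

    def test_log_ratio(self):
        assert recovery_crossing_time(2.0, 0.1, 1.0) == pytest.approx(
            np.log(2) / 0.1, rel=1e-9
        )

    @given(
        I=st.floats(0.011, 100),
        g=st.floats(0.01, 5),
        frac=st.floats(0.01, 0.99),
    )
    @settings(max_examples=200, derandomize=True)
    def test_inverse_of_decay(self, I, g, frac):
        thresh = I * frac
        t = recovery_crossing_time(I, g, thresh)
        assert decay(I, g, t) == pytest.approx(thresh, rel=1e-9)


class TestTrajectoryOracle:
    def test_event_driven_matches_fixed_step(self):
        """Analytic inter-jump decay agrees with a brute-force fixed-step
        integration over 30 days on 100 random parameter sets."""
        rng = np.random.default_rng(2024)
        dt, horizon = 1e-3, 30.0
        for _ in range(100):
            params = PhysiologyParams(
                gamma=float(rng.uniform(0.1, 1.0)),
                lam=float(rng.uniform(0.1, 1.0)),
                mean_alpha=float(rng.uniform(0.1, 1.0)),
            )
            times, sizes, _, I_post = simulate_trajectory(
                params, horizon, np.random.default_rng(rng.integers(2**31)),
                np.random.default_rng(rng.integers(2**31)),
            )
            ref = simulate_fixed_step(params.gamma, times, sizes, horizon, dt)
            grid = dt * np.arange(1, len(ref) + 1)
            exact = evaluate_trajectory(times, I_post, params.gamma, grid)
            mask = ref > 1e-6  # relative error is meaningless at ~0 levels
            if not mask.any():
                continue
            assert np.max(np.abs(exact - ref)[mask] / ref[mask]) < 1e-3

    def test_stationary_mean(self):
        """Long-run time-average converges to lam*mean_alpha/gamma."""
        rng = np.random.default_rng(77)
        horizon = 10_000.0
        for _ in range(10):
            params = PhysiologyParams(
                gamma=float(rng.uniform(0.2, 1.0)),
                lam=float(rng.uniform(0.8, 2.0)),
                mean_alpha=float(rng.uniform(0.1, 1.0)),
            )
            times, _, _, I_post = simulate_trajectory(
                params, horizon, np.random.default_rng(rng.integers(2**31)),
                np.random.default_rng(rng.integers(2**31)),
            )
            avg = trajectory_time_average(times, I_post, params.gamma, horizon)
            assert avg == pytest.approx(params.stationary_mean, rel=0.05)

    def test_bit_identical_under_same_seed(self):
        params = PhysiologyParams(gamma=0.5, lam=0.4, mean_alpha=0.3)
        a = simulate_trajectory(
            params, 100, np.random.default_rng(3), np.random.default_rng(4)
        )
        b = simulate_trajectory(
            params, 100, np.random.default_rng(3), np.random.default_rng(4)
        )
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_nonnegative_everywhere(self):
        params = PhysiologyParams(gamma=0.8, lam=2.0, mean_alpha=0.5)
        times, _, I_pre, I_post = simulate_trajectory(
            params, 500, np.random.default_rng(11), np.random.default_rng(12)
        )
        assert (I_pre >= 0).all() and (I_post > 0).all()
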
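"""Embedding parameter estimation: AMI delay, FNN dimension, radius."""

import numpy as np
import pytest

from limbrqa.embedding import (
    CalibrationError,
    EmbeddingParams,
    ami_curve,
    ami_delay,
    calibrate_radius,
    embed_multidim,
    fix_params_per_subject,
    fnn_dimension,
    params_from_frame,
    params_to_frame,
)
from limbrqa.preprocessing import MultiSeries, preprocess_session, standardize
from limbrqa.rqa import RQAConfig, measures_from_states, recurrence_rate
from limbrqa.synthetic import RegimeParams, generate_session


def noisy_sine(seed, n=2000, period=40.3, sd=0.05, channels=4):
    """Quietly noisy incommensurate-period sinusoid (fills its orbit densely)."""
    rng = np.random.default_rng(seed)
    cols = [
        np.sin(2 * np.pi * np.arange(n) / period) + rng.normal(0, sd, n)
        for _ in range(channels)
    ]
    return MultiSeries(np.column_stack(cols), 60.0, tuple(f"c{i}" for i in range(channels)))


def brute_force_mi(x, y, n_bins):
    """Independent plug-in MI oracle: explicit cell-count double loop."""
    xe = np.linspace(x.min(), x.max(), n_bins + 1)
    ye = np.linspace(y.min(), y.max(), n_bins + 1)
    xi = np.clip(np.searchsorted(xe, x, side="right") - 1, 0, n_bins - 1)
    yi = np.clip(np.searchsorted(ye, y, side="right") - 1, 0, n_bins - 1)
    n = len(x)
    mi = 0.0
    for a in range(n_bins):
        for b in range(n_bins):
            pab = np.sum((xi == a) & (yi == b)) / n
            if pab > 0:
                pa = np.sum(xi == a) / n
                pb = np.sum(yi == b) / n
                mi += pab * np.log(pab / (pa * pb))
    return mi


class TestAmiDelay:
    def test_curve_matches_brute_force_oracle(self):
        ms = noisy_sine(0, n=400, channels=1)
        curve = ami_curve(ms, max_lag=8, n_bins=10)
        x = ms.values[:, 0]
        for lag in range(1, 9):
            expected = brute_force_mi(x[: len(x) - lag], x[lag:], 10)
            assert curve[lag] == pytest.approx(expected, abs=1e-10)

    def test_recovers_quarter_period_on_sinusoids(self):
        hits = 0
        for seed in range(20):
            tau = ami_delay(noisy_sine(seed), max_lag=30)
            hits += abs(tau - 10) <= 1
        assert hits >= 18

    def test_iid_noise_yields_modal_delay_one(self):
        taus = [
            ami_delay(
                MultiSeries(
                    np.random.default_rng(seed).normal(size=(1000, 2)),
                    60.0,
                    ("a", "b"),
                ),
                max_lag=20,
            )
            for seed in range(20)
        ]
        values, counts = np.unique(taus, return_counts=True)
        assert values[np.argmax(counts)] == 1

    def test_max_lag_one_warns_and_returns_one(self):
        ms = noisy_sine(1, n=200, channels=1)
        with pytest.warns(UserWarning, match="no local minimum"):
            assert ami_delay(ms, max_lag=1) == 1

    def test_ami_bounded_by_lag_zero(self):
        curve = ami_curve(noisy_sine(2, n=500, channels=2), max_lag=15)
        assert np.all(curve[1:] <= curve[0] + 1e-12)

    def test_series_too_short_rejected(self):
        with pytest.raises(ValueError, match="max_lag"):
            ami_curve(noisy_sine(0, n=50, channels=1), max_lag=30)


class TestFnnDimension:
    def test_sine_embeds_in_two_dimensions(self):
        # noiseless: the orbit is a clean closed curve, so one extra delay
        # coordinate resolves all folding
        ms = noisy_sine(0, sd=0.0, channels=1)
        assert fnn_dimension(ms, tau=10, max_dim=6) == 2

    def test_lorenz_embeds_near_three(self):
        from scipy.integrate import solve_ivp

        def lorenz(_, y):
            return [10 * (y[1] - y[0]), y[0] * (28 - y[2]) - y[1], y[0] * y[1] - 8 / 3 * y[2]]

        sol = solve_ivp(
            lorenz, (0, 80), [1.0, 1.0, 1.0],
            t_eval=np.arange(0, 80, 0.02), rtol=1e-9, atol=1e-9,
        )
        x = standardize(sol.y[0][500:3500])
        ms = MultiSeries(x[:, None], 50.0, ("x",))
        tau = ami_delay(ms, max_lag=40)
        assert 2 <= fnn_dimension(ms, tau, max_dim=8) <= 4

    def test_noise_saturates_at_max_dim_with_warning(self):
        ms = MultiSeries(
            np.random.default_rng(5).normal(size=(1000, 2)), 60.0, ("a", "b")
        )
        with pytest.warns(UserWarning, match="never fell below"):
            assert fnn_dimension(ms, tau=1, max_dim=5) == 5


class TestEmbedMultidim:
    def test_shape_arithmetic(self):
        ms = MultiSeries(
            np.random.default_rng(0).normal(size=(100, 4)), 60.0, tuple("abcd")
        )
        st = embed_multidim(ms, tau=2, m=3)
        assert st.values.shape == (96, 12)

    def test_operating_point_shape(self):
        ms = MultiSeries(
            np.random.default_rng(1).normal(size=(3000, 4)), 60.0, tuple("abcd")
        )
        st = embed_multidim(ms, tau=1, m=14)
        assert st.values.shape == (2987, 56)

    def test_m_one_is_identity(self):
        values = np.random.default_rng(2).normal(size=(50, 3))
        ms = MultiSeries(values, 60.0, tuple("abc"))
        np.testing.assert_array_equal(embed_multidim(ms, tau=3, m=1).values, values)

    def test_lag_zero_columns_recover_input(self):
        values = np.random.default_rng(3).normal(size=(60, 2))
        ms = MultiSeries(values, 60.0, ("a", "b"))
        st = embed_multidim(ms, tau=2, m=3)
        # columns are ordered channel-major: (a lags 0..2, b lags 0..2)
        np.testing.assert_array_equal(st.values[:, 0], values[:56, 0])
        np.testing.assert_array_equal(st.values[:, 3], values[:56, 1])

    def test_insufficient_length_rejected(self):
        ms = MultiSeries(np.zeros((10, 1)) + np.arange(10)[:, None], 60.0, ("a",))
        with pytest.raises(ValueError, match="too short"):
            embed_multidim(ms, tau=5, m=3)


class TestCalibrateRadius:
    def test_reaches_target_recurrence_rate(self, small_states):
        eps = calibrate_radius(small_states, target_rr=5.0)
        rr = measures_from_states(small_states.values, eps).rr
        assert abs(rr - 5.0) <= 0.1

    def test_max_distance_gives_full_recurrence(self, small_states):
        from scipy.spatial.distance import pdist

        eps = float(pdist(small_states.values).max())
        assert recurrence_rate(small_states.values, eps) == 100.0

    def test_rr_monotone_in_epsilon(self, small_states):
        eps_grid = np.linspace(0.1, 5.0, 8)
        rates = [recurrence_rate(small_states.values, e) for e in eps_grid]
        assert all(a <= b + 1e-12 for a, b in zip(rates, rates[1:]))

    def test_tiny_epsilon_gives_zero_rate(self, small_states):
        assert recurrence_rate(small_states.values, 1e-12) == 0.0

    def test_degenerate_states_raise(self):
        with pytest.raises(CalibrationError):
            calibrate_radius(np.zeros((20, 3)), target_rr=5.0)


class TestFixParamsPerSubject:
    @staticmethod
    def _series(subject, visit, task, seed):
        params = RegimeParams("rhythmic" if task == "rattle" else "unstructured", 20.0)
        session = generate_session(
            params, seed=seed, subject_id=subject, visit=visit, task=task, rate_hz=12.0
        )
        return preprocess_session(session)

    def test_anchored_at_earliest_visit_and_reused(self):
        series = [
            self._series("S01", v, "rattle", seed)
            for seed, v in enumerate(["T2", "T1", "T3", "T4"])
        ]
        params = fix_params_per_subject(series, tau=1, m=4)
        assert params[("S01", "rattle")].anchor_visit == "T1"
        assert len(params) == 1  # one frozen set for all four visits

    def test_subject_first_seen_at_t2(self):
        series = [self._series("S02", "T2", "rattle", 5)]
        params = fix_params_per_subject(series, tau=1, m=4)
        assert params[("S02", "rattle")].anchor_visit == "T2"

    def test_subjects_get_independent_radii(self):
        series = [
            self._series("S01", "T1", "rattle", 1),
            self._series("S02", "T1", "rattle", 2),
        ]
        params = fix_params_per_subject(series, tau=1, m=4)
        assert params[("S01", "rattle")].epsilon != params[("S02", "rattle")].epsilon

    def test_round_trip_through_frame(self):
        series = [self._series("S01", "T1", "rattle", 1)]
        params = fix_params_per_subject(series, tau=1, m=4)
        frame = params_to_frame(params)
        assert params_from_frame(frame) == params

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            EmbeddingParams(tau=0, m=4, epsilon=1.0)
        with pytest.raises(ValueError):
            EmbeddingParams(tau=1, m=4, epsilon=-1.0)
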
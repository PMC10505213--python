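"""LIV, temporal autocorrelation and OCDS estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from doct.metrics import (
    OCDSE_WINDOW_MS,
    OCDSL_WINDOW_MS,
    AutocorrelationCurve,
    InsufficientDataError,
    compute_acf,
    compute_dynamics_volume,
    compute_liv,
    fit_ocds,
)
from doct.volume import TimeSequenceVolume, to_db

from conftest import tiny_protocol

DT = 204.8


class TestLIV:
    def test_constant_sequence_has_zero_variance(self):
        assert compute_liv(np.full(32, 5.0)) == 0.0

    def test_alternating_sequence(self):
        # deviations are +-1 dB around the mean of 1 dB -> mean square 1
        seq = np.tile([0.0, 2.0], 16)
        assert compute_liv(seq, n_frames=32) == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [8, 32])
    def test_iid_gaussian_expectation_matches_divisor_n_variance(self, n):
        # E[LIV] = sigma^2 (N-1)/N for i.i.d. Gaussian dB noise
        sigma = 3.0
        rng = np.random.default_rng(42)
        samples = rng.normal(0.0, sigma, size=(10_000, n))
        livs = ((samples - samples.mean(axis=1, keepdims=True)) ** 2).mean(axis=1)
        expected = sigma**2 * (n - 1) / n
        assert livs.mean() == pytest.approx(expected, rel=0.02)
        # the estimator itself agrees with the brute-force row computation
        assert compute_liv(samples[0]) == pytest.approx(livs[0], rel=1e-12)

    def test_too_few_frames_rejected(self):
        with pytest.raises(InsufficientDataError):
            compute_liv(np.array([1.0]))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            compute_liv(np.array([1.0, np.nan, 2.0]))


def _pearson(a, b):
    return np.corrcoef(a, b)[0, 1]


class TestACF:
    def test_rho_at_zero_delay_is_one(self):
        curve = compute_acf(np.random.default_rng(0).normal(size=32), dt_ms=DT)
        assert curve.rho[0] == 1.0
        assert curve.valid[0]

    def test_alternating_sequence_has_lag1_anticorrelation(self):
        seq = np.tile([0.0, 2.0], 8)
        curve = compute_acf(seq, dt_ms=DT)
        assert curve.rho[1] == pytest.approx(-1.0)
        assert curve.rho[1] == pytest.approx(_pearson(seq[:-1], seq[1:]))

    def test_matches_per_lag_pearson_oracle(self):
        seq = np.random.default_rng(3).normal(size=24)
        curve = compute_acf(seq, dt_ms=DT)
        for lag in range(1, 22):
            assert curve.rho[lag] == pytest.approx(
                _pearson(seq[:-lag], seq[lag:]), abs=1e-12
            )

    def test_constant_sequence_flagged_invalid(self):
        curve = compute_acf(np.full(16, 2.5), dt_ms=DT)
        assert not curve.valid[1:].any()

    @given(
        a=st.floats(0.1, 10.0),
        b=st.floats(-50.0, 50.0),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b, seed):
        seq = np.random.default_rng(seed).normal(size=32)
        base = compute_acf(seq, dt_ms=DT)
        scaled = compute_acf(a * seq + b, dt_ms=DT)
        np.testing.assert_allclose(scaled.rho, base.rho, atol=1e-8)

    def test_bounded_by_one_where_valid(self):
        seq = np.random.default_rng(9).exponential(size=32)
        curve = compute_acf(seq, dt_ms=DT)
        assert np.all(np.abs(curve.rho[curve.valid]) <= 1.0 + 1e-9)


class TestOcdsFit:
    def make_curve(self, rho_fn, n=32):
        delays = np.arange(n) * DT
        rho = rho_fn(delays)
        rho[0] = 1.0
        return AutocorrelationCurve(delays, rho, np.ones(n, dtype=bool))

    def test_flat_curve_has_zero_decay_speed(self):
        curve = self.make_curve(lambda d: np.full_like(d, 0.5))
        assert fit_ocds(curve, OCDSL_WINDOW_MS).speed == 0.0

    def test_collinear_points_recover_exact_slope(self):
        # rho drops by 0.1 per 204.8 ms step -> decay speed 0.1/204.8
        curve = self.make_curve(lambda d: 1.0 - 0.1 * d / DT)
        fit = fit_ocds(curve, OCDSL_WINDOW_MS)
        expected = 0.1 / DT
        assert fit.valid
        assert abs(fit.speed - expected) / expected <= 1e-12

    def test_rising_curve_gives_negative_speed_unclipped(self):
        curve = self.make_curve(lambda d: 0.2 + 1e-4 * d)
        assert fit_ocds(curve, OCDSL_WINDOW_MS).speed < 0.0

    def test_window_with_fewer_than_two_grid_points_rejected(self):
        curve = self.make_curve(lambda d: np.exp(-d / 1000.0))
        with pytest.raises(ValueError, match="grid delays"):
            fit_ocds(curve, (50.0, 60.0))

    def test_invalid_curve_in_window_returns_zero_with_flag(self):
        curve = self.make_curve(lambda d: np.exp(-d / 1000.0))
        curve.valid[3] = False
        fit = fit_ocds(curve, OCDSL_WINDOW_MS)
        assert fit.speed == 0.0 and not fit.valid

    def test_white_noise_decay_speed_is_zero_on_average(self):
        rng = np.random.default_rng(123)
        n_pixels = 10_000
        speeds = np.empty(n_pixels)
        seqs = rng.normal(size=(n_pixels, 32))
        for i in range(n_pixels):
            speeds[i] = fit_ocds(compute_acf(seqs[i], dt_ms=DT), OCDSL_WINDOW_MS).speed
        # Monte-Carlo confidence band around 0
        assert abs(speeds.mean()) < 4 * speeds.std() / np.sqrt(n_pixels)


class TestDynamicsVolume:
    def make_volume(self, data, dt_ms=DT):
        protocol = tiny_protocol(n_repeats=data.shape[1], dt_ms=dt_ms, ny=data.shape[0])
        return TimeSequenceVolume(data=data, protocol=protocol, scale="dB")

    def test_zero_variance_background_yields_zero_maps(self):
        data = np.zeros((2, 32, 4, 4))
        data[0, :, 0, 0] = np.random.default_rng(0).normal(size=32)
        maps = compute_dynamics_volume(self.make_volume(data))
        assert maps.liv[0, 0, 0] > 0
        assert maps.ocds_l_valid[0, 0, 0]
        assert maps.liv[1].max() == 0.0
        assert maps.ocds_l[1].max() == 0.0
        assert not maps.ocds_l_valid[1].any()

    def test_matches_per_pixel_reference_path(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(2, 32, 3, 3))
        maps = compute_dynamics_volume(self.make_volume(data))
        y, z, x = 1, 2, 0
        seq = data[y, :, z, x]
        assert maps.liv[y, z, x] == pytest.approx(compute_liv(seq), rel=1e-12)
        ref = fit_ocds(compute_acf(seq, dt_ms=DT), OCDSL_WINDOW_MS)
        assert maps.ocds_l[y, z, x] == pytest.approx(ref.speed, rel=1e-10)
        assert maps.mean_intensity_db[y, z, x] == pytest.approx(seq.mean())

    def test_linear_scale_input_rejected(self):
        vol = TimeSequenceVolume(
            data=np.ones((1, 32, 2, 2)), protocol=tiny_protocol(n_repeats=32, ny=1)
        )
        with pytest.raises(ValueError, match="dB-scaled"):
            compute_dynamics_volume(vol)

    def test_early_window_incompatible_with_coarse_grid(self):
        vol = self.make_volume(np.random.default_rng(1).normal(size=(1, 32, 2, 2)))
        with pytest.raises(ValueError, match="OCDS_e"):
            compute_dynamics_volume(vol, compute_ocds_e=True)

    def test_liv_invariant_under_positive_intensity_scaling(self):
        rng = np.random.default_rng(8)
        linear = rng.exponential(size=(1, 32, 4, 4))
        protocol = tiny_protocol(n_repeats=32, ny=1)
        v1 = TimeSequenceVolume(data=linear, protocol=protocol)
        v2 = TimeSequenceVolume(data=7.3 * linear, protocol=protocol)
        m1 = compute_dynamics_volume(to_db(v1, floor=1e-12))
        m2 = compute_dynamics_volume(to_db(v2, floor=1e-12))
        np.testing.assert_allclose(m2.liv, m1.liv, rtol=1e-9)
        np.testing.assert_allclose(m2.ocds_l, m1.ocds_l, atol=1e-12)
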
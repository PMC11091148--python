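import numpy as np
import pytest
from scipy.signal import lfilter

from ecgcancel.bss import (
    BssConfig,
    MixingSystem,
    build_workspace,
    convolutive_mix,
    cost,
    predicted_xcorr,
    separate,
    update_weights,
    xcorr_lag,
)
from ecgcancel.errors import ParameterError
from ecgcancel.signals import Signal1D


def _impulse(n: int) -> np.ndarray:
    x = np.zeros(n)
    x[0] = 1.0
    return x


class TestConvolutiveMix:
    def test_impulse_through_h21(self):
        s1 = Signal1D(_impulse(16), 500.0)
        s2 = Signal1D(np.zeros(16), 500.0)
        x1, x2 = convolutive_mix(s1, s2, MixingSystem([0.0], [0.3]))
        np.testing.assert_allclose(x1.samples, s1.samples)
        np.testing.assert_allclose(x2.samples, 0.3 * s1.samples)

    def test_zero_coupling_is_identity(self, white_pair):
        s1, s2 = white_pair
        x1, x2 = convolutive_mix(s1, s2, MixingSystem([0.0, 0.0], [0.0, 0.0]))
        np.testing.assert_array_equal(x1.samples, s1.samples)
        np.testing.assert_array_equal(x2.samples, s2.samples)

    def test_two_tap_impulse_response(self):
        s1 = Signal1D(np.zeros(8), 500.0)
        s2 = Signal1D(_impulse(8), 500.0)
        x1, _ = convolutive_mix(s1, s2, MixingSystem([0.4, 0.2], [0.0, 0.0]))
        np.testing.assert_allclose(x1.samples[:3], [0.4, 0.2, 0.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            convolutive_mix(
                Signal1D(np.zeros(10) + 1, 500.0),
                Signal1D(np.zeros(11) + 1, 500.0),
                MixingSystem([0.1], [0.1]),
            )


class TestXcorrLag:
    @pytest.mark.parametrize(
        "a,b,l,expected",
        [
            ([1, -1, 1, -1], [1, -1, 1, -1], 0, 1.0),
            ([1, 1, -1, -1], [1, -1, 1, -1], 0, 0.0),
            ([1, 0, 0, 0], [0, 1, 0, 0], 1, 0.25),
        ],
    )
    def test_known_values(self, a, b, l, expected):
        assert xcorr_lag(np.array(a, float), np.array(b, float), l) == pytest.approx(expected)

    def test_symmetry_under_argument_swap(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal(64), rng.standard_normal(64)
        for l in (-5, -1, 0, 3, 10):
            assert xcorr_lag(a, b, l) == pytest.approx(xcorr_lag(b, a, -l))

    def test_excessive_lag_rejected(self):
        with pytest.raises(ParameterError):
            xcorr_lag(np.zeros(4), np.zeros(4), 4)


class TestWorkspace:
    def test_degenerate_shapes_q0_single_lag(self, white_pair):
        x1, x2 = white_pair
        ws = build_workspace(x1, x2, BssConfig(q=0, l1=0, l2=0))
        a = x1.samples - x1.samples.mean()
        b = x2.samples - x2.samples.mean()
        assert ws.r_x1x2.shape == (1,)
        assert ws.r_x1x2[0] == pytest.approx(xcorr_lag(a, b, 0))

    def test_matrix_shapes(self, white_pair):
        x1, x2 = white_pair
        ws = build_workspace(x1, x2, BssConfig(q=2, l1=-5, l2=5))
        assert ws.q_plus_x2x2.shape == (3, 11)
        assert ws.q_minus_x1x1.shape == (3, 11)
        assert ws.r_x2x1.shape == (5, 11)

    def test_white_noise_off_lag_autocorrelation_decays(self, white_pair):
        x1, x2 = white_pair
        n = x2.n
        ws = build_workspace(x1, x2, BssConfig(q=2, l1=-5, l2=5))
        lags = np.arange(-5, 6)
        for i in range(3):
            off = ws.q_plus_x2x2[i][(lags + i) != 0]
            assert np.max(np.abs(off)) < 3 / np.sqrt(n)

    def test_too_short_signal_rejected(self):
        short = Signal1D(np.arange(30, dtype=float), 500.0)
        with pytest.raises(ParameterError):
            build_workspace(short, short, BssConfig(q=4, l1=-25, l2=25))


class TestPredictedXcorr:
    def test_zero_weights_reproduce_input_cross_correlation(self, white_pair):
        x1, x2 = white_pair
        cfg = BssConfig(q=3, l1=-10, l2=10)
        ws = build_workspace(x1, x2, cfg)
        pred = predicted_xcorr(ws, np.zeros(4), np.zeros(4))
        np.testing.assert_array_equal(pred, ws.r_x1x2)

    @pytest.mark.parametrize("q", [0, 1, 3])
    def test_matches_brute_force_filtering(self, q, white_pair):
        """Closed-form expansion vs explicitly filtering the outputs."""
        x1, x2 = white_pair
        mix = MixingSystem([0.4, 0.2], [0.3, 0.1])
        x1, x2 = convolutive_mix(x1, x2, mix)
        cfg = BssConfig(q=q, l1=-15, l2=15)
        ws = build_workspace(x1, x2, cfg)
        rng = np.random.default_rng(q)
        w1 = rng.uniform(-0.5, 0.5, q + 1)
        w2 = rng.uniform(-0.5, 0.5, q + 1)
        pred = predicted_xcorr(ws, w1, w2)
        a = x1.samples - x1.samples.mean()
        b = x2.samples - x2.samples.mean()
        y1 = a + lfilter(w1, [1.0], b)
        y2 = b + lfilter(w2, [1.0], a)
        emp = np.array([xcorr_lag(y1, y2, l) for l in range(-15, 16)])
        assert np.max(np.abs(pred - emp)) < 10 / x1.n

    def test_affine_in_w1_at_fixed_w2(self, white_pair):
        x1, x2 = white_pair
        cfg = BssConfig(q=2, l1=-5, l2=5)
        ws = build_workspace(x1, x2, cfg)
        rng = np.random.default_rng(9)
        w1 = rng.uniform(-0.3, 0.3, 3)
        w2 = rng.uniform(-0.3, 0.3, 3)
        base = predicted_xcorr(ws, np.zeros(3), w2)
        d1 = predicted_xcorr(ws, w1, w2) - base
        d2 = predicted_xcorr(ws, 2 * w1, w2) - base
        np.testing.assert_allclose(d2, 2 * d1, atol=1e-12)

    def test_wrong_weight_length_rejected(self, white_pair):
        x1, x2 = white_pair
        ws = build_workspace(x1, x2, BssConfig(q=2, l1=-5, l2=5))
        with pytest.raises(ParameterError):
            predicted_xcorr(ws, np.zeros(2), np.zeros(3))


class TestCost:
    @pytest.mark.parametrize(
        "r,expected",
        [([0.0, 0.0, 0.0], 0.0), ([0.3, -0.4], 0.25)],
    )
    def test_sum_of_squares(self, r, expected):
        assert cost(np.array(r)) == pytest.approx(expected)

    def test_quadratic_scaling(self):
        r = np.array([0.1, -0.2, 0.3])
        assert cost(2 * r) == pytest.approx(4 * cost(r))

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            cost(np.array([]))


class TestUpdateWeights:
    def test_independent_inputs_give_near_zero_weights(self, white_pair):
        x1, x2 = white_pair
        cfg = BssConfig(q=2, l1=-10, l2=10)
        ws = build_workspace(x1, x2, cfg)
        w1, w2 = update_weights(ws, np.zeros(3), np.zeros(3), cfg)
        bound = 5 / np.sqrt(x1.n)
        assert np.linalg.norm(w1) < bound
        assert np.linalg.norm(w2) < bound

    def test_scalar_case_fixed_point_recovers_minus_c(self):
        """q=0, single lag, x1 = s1 + c*s2, x2 = s2: the hand-solved
        update converges to w1 = -c, w2 = 0."""
        rng = np.random.default_rng(4)
        n, c = 10_000, 0.6
        s1 = rng.standard_normal(n)
        s2 = rng.standard_normal(n)
        x1 = Signal1D(s1 + c * s2, 500.0)
        x2 = Signal1D(s2, 500.0)
        cfg = BssConfig(q=0, l1=0, l2=0, max_iter=200, conv_tol=1e-12)
        ws = build_workspace(x1, x2, cfg)
        w1, w2 = np.zeros(1), np.zeros(1)
        # hand-derived scalar update: w1' = -(r + Qm*w2) / (Qp + R*w2)
        r = ws.r_x1x2[0]
        qp = ws.q_plus_x2x2[0, 0]
        qm = ws.q_minus_x1x1[0, 0]
        rr = ws.r_x2x1[0, 0]
        w1_hand = -(r + qm * w2[0]) / (qp + rr * w2[0])
        w1_code, _ = update_weights(ws, w1, w2, cfg)
        assert w1_code[0] == pytest.approx(w1_hand, rel=1e-6)
        for _ in range(50):
            w1, w2 = update_weights(ws, w1, w2, cfg)
        assert w1[0] == pytest.approx(-c, abs=0.05)
        assert w2[0] == pytest.approx(0.0, abs=0.05)

    def test_update_is_a_fixed_point_after_convergence(self, white_pair):
        s1, s2 = white_pair
        x1, x2 = convolutive_mix(s1, s2, MixingSystem([0.4, 0.2], [0.3, 0.1]))
        cfg = BssConfig(q=1, l1=-10, l2=10, max_iter=5000, conv_tol=1e-12)
        res = separate(x1, x2, cfg)
        w1a, w2a = update_weights(build_workspace(x1, x2, cfg), res.w1, res.w2, cfg)
        assert np.max(np.abs(w1a - res.w1)) < 1e-4
        assert np.max(np.abs(w2a - res.w2)) < 1e-4


class TestSeparate:
    def test_zero_partner_passes_through(self):
        rng = np.random.default_rng(6)
        x1 = Signal1D(rng.standard_normal(2000), 500.0)
        x2 = Signal1D(np.zeros(2000), 500.0)
        res = separate(x1, x2, BssConfig(q=2, l1=-5, l2=5))
        np.testing.assert_allclose(res.w1, 0.0, atol=1e-12)
        np.testing.assert_array_equal(res.y1.samples, x1.samples)

    def test_cost_trajectory_monotone_overall(self, ecg_default, audio_default):
        res = separate(ecg_default, audio_default, BssConfig())
        traj = np.array(res.cost_trajectory)
        assert np.all(np.isfinite(traj))
        assert traj[-1] <= traj[0]

    def test_correlated_inputs_are_decorrelated_tenfold(self, ecg_default, audio_default):
        x1, x2 = convolutive_mix(
            ecg_default, audio_default, MixingSystem([0.4, 0.2], [0.3, 0.1])
        )
        res = separate(x1, x2, BssConfig())
        assert res.cost_trajectory[-1] <= 0.1 * res.cost_trajectory[0]

    def test_weight_recovery_sharpens_with_sample_size(self):
        """Estimated weights approach (-h12, -h21) within sampling error;
        at n = 10^5 the displacement is well inside +-0.05."""
        rng = np.random.default_rng(0)
        n = 100_000
        s1 = Signal1D(rng.standard_normal(n), 500.0)
        s2 = Signal1D(rng.standard_normal(n), 500.0)
        h12, h21 = np.array([0.4, 0.2]), np.array([0.3, 0.1])
        x1, x2 = convolutive_mix(s1, s2, MixingSystem(h12, h21))
        res = separate(x1, x2, BssConfig(q=1, l1=-10, l2=10, max_iter=20000, conv_tol=1e-12))
        assert np.max(np.abs(res.w1 + h12)) < 0.05
        assert np.max(np.abs(res.w2 + h21)) < 0.05

    def test_scale_equivariance(self, white_pair):
        s1, s2 = white_pair
        x1, x2 = convolutive_mix(s1, s2, MixingSystem([0.4, 0.2], [0.3, 0.1]))
        cfg = BssConfig(q=1, l1=-10, l2=10, max_iter=50)
        res = separate(x1, x2, cfg)
        alpha = 3.0
        res_s = separate(
            Signal1D(alpha * x1.samples, x1.fs),
            Signal1D(alpha * x2.samples, x2.fs),
            cfg,
        )
        np.testing.assert_allclose(res_s.w1, res.w1, atol=1e-8)
        np.testing.assert_allclose(res_s.y1.samples, alpha * res.y1.samples, rtol=1e-8)

    def test_non_convergence_is_flagged_not_raised(self, ecg_default, audio_default):
        res = separate(ecg_default, audio_default, BssConfig(max_iter=1, conv_tol=1e-30))
        assert res.converged is False
        assert res.iterations == 1
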
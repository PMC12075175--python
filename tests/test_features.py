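"""Descriptor formulas vs literal brute-force evaluation, tensor assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import emgband as eb
from emgband.features import (
    FeatureConfig, FeatureStandardizer, feature_isd, feature_isd_minus_rsc,
    feature_mean_dd2, feature_mean_log_kernel, feature_mean_sqrt,
    sliding_features, window_feature_vector,
)
from emgband.preprocess import WindowSpec
from emgband.recording import ConfigError, EmgRecording


def brute_force_features(x, theta=None, eps_log=1e-8):
    """Literal summation of the six descriptor formulas, coded independently."""
    x = np.asarray(x, float)
    n = len(x)
    th = n if theta is None else theta
    isd = sum(x[i] ** 2 for i in range(n))
    dd1 = [x[i + 1] - x[i] for i in range(n - 1)]
    dd2 = [x[i + 2] - 2 * x[i + 1] + x[i] for i in range(n - 2)]
    f2 = isd - sum(v ** 2 for v in dd1) / th
    f3 = isd - sum(v ** 2 for v in dd2) / th
    f4 = abs(np.exp(sum(np.log(abs(v) + eps_log) for v in x) / n))
    f5 = sum(abs(v) ** 0.5 for v in x) / n
    f6 = sum(dd2) / n
    return np.array([isd, f2, f3, f4, f5, f6])


class TestHandValues:
    def test_isd_of_1_2_3_is_14(self):
        assert feature_isd([1, 2, 3]) == 14

    def test_isd_zero_vector(self):
        assert feature_isd(np.zeros(10)) == 0.0

    def test_isd_quadratic_scaling(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        for a in rng.uniform(-5, 5, 5):
            assert feature_isd(a * x) == pytest.approx(a * a * feature_isd(x), rel=1e-12)

    def test_isd_minus_rsc_first_order_hand_value(self):
        # [1,2,4]: ISD=21, DD1=[1,2], 21 - (1+4)/3
        assert feature_isd_minus_rsc([1, 2, 4], 1, 3.0) == pytest.approx(21 - 5 / 3)

    def test_isd_minus_rsc_second_order_hand_value(self):
        # DD2 = [4 - 4 + 1] = [1]; 21 - 1/3
        assert feature_isd_minus_rsc([1, 2, 4], 2, 3.0) == pytest.approx(21 - 1 / 3)

    def test_constant_window_keeps_pure_isd(self):
        x = np.full(20, 3.0)
        for order in (1, 2):
            assert feature_isd_minus_rsc(x, order, 20.0) == pytest.approx(feature_isd(x))

    def test_log_kernel_constant_e(self):
        assert feature_mean_log_kernel([np.e] * 3, 1e-15) == pytest.approx(np.e, rel=1e-9)

    def test_log_kernel_geometric_mean(self):
        assert feature_mean_log_kernel([1.0, 4.0], 1e-15) == pytest.approx(2.0, rel=1e-9)

    def test_log_kernel_sign_symmetric(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(40)
        assert feature_mean_log_kernel(x) == pytest.approx(feature_mean_log_kernel(-x))

    def test_mean_sqrt_hand_value(self):
        assert feature_mean_sqrt([4.0, 9.0]) == pytest.approx(2.5)

    def test_mean_sqrt_magnitude_convention(self):
        assert feature_mean_sqrt([-4.0, -9.0]) == pytest.approx(2.5)

    def test_mean_dd2_linear_ramp_is_zero(self):
        assert feature_mean_dd2([0.0, 1.0, 2.0, 3.0]) == 0.0

    def test_mean_dd2_hand_values(self):
        assert feature_mean_dd2([0.0, 0.0, 1.0]) == pytest.approx(1 / 3)
        x = np.arange(5.0) ** 2
        assert feature_mean_dd2(x) == pytest.approx(6 / 5)

    def test_invalid_inputs(self):
        with pytest.raises(ConfigError):
            feature_isd([])
        with pytest.raises(ConfigError):
            feature_isd_minus_rsc([1, 2, 3], 1, 0.0)
        with pytest.raises(ConfigError):
            feature_mean_dd2([1, 2])


class TestBruteForceOracle:
    def test_thousand_random_windows_match_to_1e10(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(3, 40)
            x = rng.standard_normal(n) * rng.uniform(0.1, 10)
            got = window_feature_vector(x)
            want = brute_force_features(x)
            np.testing.assert_allclose(got, want, rtol=1e-10)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=30), st.integers(0, 2 ** 31))
    def test_property_windows_match_brute_force(self, xs, seed):
        x = np.array(xs)
        got = window_feature_vector(x)
        want = brute_force_features(x)
        np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-9)

    def test_sliding_implementation_matches_per_window(self):
        rng = np.random.default_rng(7)
        sig = rng.standard_normal((500, 3))
        L, S = 50, 7
        fast = sliding_features(sig, L, S)
        for w in range(fast.shape[0]):
            for c in range(3):
                want = brute_force_features(sig[w * S:w * S + L, c])
                np.testing.assert_allclose(fast[w, c], want, rtol=1e-9, atol=1e-12)


class TestTensorAssembly:
    def test_single_sample_shape(self):
        rng = np.random.default_rng(0)
        rec = EmgRecording(data=rng.standard_normal((890, 4)), fs=1067.0,
                           labels=np.zeros(890))
        wspec = WindowSpec(length_ms=300 / 1067 * 1000, step_ms=10 / 1067 * 1000)
        feats = eb.extract_feature_tensor(rec, wspec, time_steps=60)
        assert feats.tensor.shape == (1, 60, 4, 6)

    def test_21_channel_axis(self, feats_medium):
        assert feats_medium.tensor.shape[2] == 21
        assert feats_medium.tensor.shape[1] == 60
        assert feats_medium.tensor.shape[3] == 6

    def test_rest_only_recording_labels(self):
        rng = np.random.default_rng(1)
        rec = EmgRecording(data=rng.standard_normal((3000, 2)), fs=1067.0,
                           labels=np.full(3000, 5))
        feats = eb.extract_feature_tensor(rec, time_steps=30)
        assert (feats.labels == 5).all()

    def test_mixed_blocks_dropped(self):
        rng = np.random.default_rng(2)
        labels = np.zeros(4000, dtype=int)
        labels[2000:] = 1
        rec = EmgRecording(data=rng.standard_normal((4000, 1)), fs=1067.0, labels=labels)
        feats = eb.extract_feature_tensor(rec, time_steps=18)
        assert set(np.unique(feats.labels)) <= {0, 1}
        # windows spanning the boundary never produce a sample of their own
        assert feats.n_samples <= (4000 - 300) // 10 // 18

    def test_channel_independence(self):
        rng = np.random.default_rng(3)
        sig = rng.standard_normal((600, 4))
        perm = np.array([3, 1, 0, 2])
        a = sliding_features(sig, 60, 10)[:, perm]
        b = sliding_features(sig[:, perm], 60, 10)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_standardizer_zero_mean_unit_sd(self, feats_medium):
        z = FeatureStandardizer().fit_transform(feats_medium.tensor)
        np.testing.assert_allclose(z.mean(axis=(0, 1)), 0.0, atol=1e-6)
        np.testing.assert_allclose(z.std(axis=(0, 1)), 1.0, atol=1e-6)

    def test_too_short_recording_rejected(self):
        rec = EmgRecording(data=np.zeros((500, 1)), fs=1067.0, labels=np.zeros(500))
        with pytest.raises(ConfigError):
            eb.extract_feature_tensor(rec, time_steps=60)
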
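"""Generator ground truth: schedule geometry, SNR calibration, spectra."""

import numpy as np
import pytest
from scipy import signal as sps, stats

import emgband as eb
from emgband.recording import ConfigError
from emgband.synthetic import GestureSpatialModel, ProtocolConfig


class TestSchedule:
    def test_default_protocol_yields_60_trials(self):
        sch = eb.generate_trial_schedule(ProtocolConfig())
        assert len(sch) == 60

    def test_single_trial_schedule(self):
        p = ProtocolConfig(n_gestures=1, reps_per_gesture=1)
        sch = eb.generate_trial_schedule(p)
        assert len(sch) == 1
        g, start, end = sch[0]
        assert end - start == int(round(p.move_s * p.fs))

    def test_movement_interval_spans_6402_samples(self):
        sch = eb.generate_trial_schedule(ProtocolConfig())
        assert all(end - start == 6402 for _, start, end in sch)

    def test_intervals_ordered_disjoint_and_balanced(self):
        p = ProtocolConfig(reps_per_gesture=3, seed=9)
        sch = eb.generate_trial_schedule(p)
        starts = [s for _, s, _ in sch]
        assert starts == sorted(starts)
        for (_, _, e0), (_, s1, _) in zip(sch, sch[1:]):
            assert s1 >= e0
        counts = np.bincount([g for g, _, _ in sch], minlength=p.n_gestures)
        assert (counts == p.reps_per_gesture).all()

    def test_each_repetition_block_contains_every_gesture(self):
        p = ProtocolConfig(reps_per_gesture=4, seed=3)
        sch = eb.generate_trial_schedule(p)
        for b in range(p.reps_per_gesture):
            block = sorted(g for g, _, _ in sch[b * p.n_gestures:(b + 1) * p.n_gestures])
            assert block == list(range(p.n_gestures))


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"move_s": 0}, {"rest_s": -1}, {"n_nodes": 0}, {"fs": 500.0},
    ])
    def test_invalid_protocol_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            ProtocolConfig(**kwargs)

    def test_rest_gesture_must_be_silent(self):
        act = np.ones((3, 6))
        with pytest.raises(ConfigError):
            GestureSpatialModel(activation=act)

    def test_active_gesture_needs_a_channel(self):
        act = np.zeros((3, 6))
        act[0, 0] = 1.0
        with pytest.raises(ConfigError):
            GestureSpatialModel(activation=act)


class TestSession:
    def test_label_conservation(self, small_protocol, small_session):
        p = small_protocol
        sch = eb.generate_trial_schedule(p)
        moved = sum(end - start for _, start, end in sch)
        assert moved == p.n_trials * p.move_samples
        non_rest = int(np.sum(small_session.labels != p.rest_id))
        assert non_rest == (p.n_gestures - 1) * p.reps_per_gesture * p.move_samples

    def test_reproducibility_bit_identical(self):
        p = ProtocolConfig(n_gestures=2, reps_per_gesture=1, move_s=1, rest_s=1, seed=42)
        a = eb.generate_session(p)
        b = eb.generate_session(p)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.labels, b.labels)

    def test_different_seed_differs(self):
        p1 = ProtocolConfig(n_gestures=2, reps_per_gesture=1, move_s=1, rest_s=1, seed=1)
        p2 = ProtocolConfig(n_gestures=2, reps_per_gesture=1, move_s=1, rest_s=1, seed=2)
        assert not np.array_equal(eb.generate_session(p1).data, eb.generate_session(p2).data)

    def test_rest_only_session_is_pure_noise(self):
        p = ProtocolConfig(n_gestures=1, reps_per_gesture=10, move_s=3, rest_s=3, seed=5)
        spatial = GestureSpatialModel(activation=np.zeros((1, p.n_channels)),
                                      noise_floor_sd=1.0)
        rec = eb.generate_session(p, spatial)
        assert rec.duration_s >= 60
        var = rec.data.var(axis=0)
        assert np.all(np.abs(var - 1.0) < 0.05)

    def test_snr_calibration_variance_ratio(self):
        # snr_target 9.54 dB -> sigma_on^2/sigma_off^2 = 1 + 10^0.954 ~= 10
        p = ProtocolConfig(n_gestures=2, reps_per_gesture=10, move_s=1, rest_s=1,
                           n_nodes=1, channels_per_node=3, seed=7)
        spatial = GestureSpatialModel(
            activation=np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 0.0]]),
            snr_target_db=9.54, trial_gain_jitter=0.0, trial_shift_sd=0.0)
        rec = eb.generate_session(p, spatial)
        sch = [s for s in eb.generate_trial_schedule(p) if s[0] == 0]
        ramp = int(0.15 * p.fs)
        on = np.concatenate([rec.data[s + ramp:e - ramp, 0] for _, s, e in sch])
        off = rec.data[rec.labels == p.rest_id, 0]
        ratio = on.var() / off.var()
        assert ratio == pytest.approx(10.0, rel=0.10)

    def test_carrier_power_confined_to_band(self):
        p = ProtocolConfig(n_gestures=2, reps_per_gesture=1, move_s=60, rest_s=1,
                           n_nodes=1, channels_per_node=1, seed=3)
        spatial = GestureSpatialModel(activation=np.array([[1.0], [0.0]]),
                                      noise_floor_sd=1e-6, snr_target_db=40.0,
                                      trial_gain_jitter=0.0, trial_shift_sd=0.0)
        rec = eb.generate_session(p, spatial)
        start, end = next((s, e) for g, s, e in eb.generate_trial_schedule(p) if g == 0)
        seg = rec.data[start + int(p.fs):end - int(p.fs), 0]  # steady movement
        f, pxx = sps.periodogram(seg, fs=p.fs)
        inside = pxx[(f >= 25) & (f <= 360)].sum()
        assert inside / pxx.sum() > 0.95

    def test_silent_channels_carry_only_noise_floor(self):
        p = ProtocolConfig(n_gestures=2, reps_per_gesture=6, move_s=2, rest_s=2,
                           n_nodes=2, channels_per_node=3, seed=11)
        act = np.zeros((2, 6))
        act[0, :3] = 1.0
        spatial = GestureSpatialModel(activation=act, trial_gain_jitter=0.0,
                                      trial_shift_sd=0.0)
        rec = eb.generate_session(p, spatial)
        on = rec.labels == 0
        silent_on = rec.data[on, 5]
        rest = rec.data[rec.labels == p.rest_id, 5]
        # two-sample variance comparison (Levene) at alpha = 0.01
        _, pval = stats.levene(silent_on, rest)
        assert pval > 0.01
        # and the active channel is unambiguously hotter
        assert rec.data[on, 0].var() > 5 * rest.var()
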
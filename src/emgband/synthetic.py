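"""Synthetic armband sessions with known spatial ground truth.

The generator emulates a cued-gesture recording protocol: six movements
(power grip, lateral pinch, tripod, pointer, open, rest), ten repetitions
each, 6 s of movement followed by 6 s of rest per trial, recorded by a
7-node x 3-channel armband at 1,067 Hz.  Surface EMG is modelled
phenomenologically as band-limited Gaussian noise (the carrier, 30-350 Hz)
amplitude-modulated by a smooth contraction envelope, on top of a white
baseline noise floor.  Each gesture owns a per-channel gain pattern, so the
spatial information content of a session is fully controllable and known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .recording import ConfigError, EmgRecording, default_channel_map

GESTURE_NAMES = ("power", "lateral", "tripod", "pointer", "open", "rest")

#: duration of the raised-cosine contraction onset/offset ramp, seconds
RAMP_S = 0.1


@dataclass
class ProtocolConfig:
    """Recording-protocol geometry and timing.

    Defaults reproduce the study protocol: 6 gestures x 10 repetitions,
    6 s movement + 6 s rest per trial, 21 channels at 1,067 Hz.  The last
    gesture id (``n_gestures - 1``) is the rest class; its "movement"
    interval is labelled rest and carries no muscle activity.
    """

    n_gestures: int = 6
    reps_per_gesture: int = 10
    move_s: float = 6.0
    rest_s: float = 6.0
    fs: float = 1067.0
    n_nodes: int = 7
    channels_per_node: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.move_s <= 0 or self.rest_s <= 0:
            raise ConfigError("move_s and rest_s must be positive")
        if self.n_gestures < 1 or self.reps_per_gesture < 1:
            raise ConfigError("need at least one gesture and one repetition")
        if self.n_nodes * self.channels_per_node < 1:
            raise ConfigError("channel count must be positive")
        if self.fs <= 2 * 350.0:
            raise ConfigError(f"fs={self.fs} too low for a 30-350 Hz carrier band")

    @property
    def n_channels(self) -> int:
        return self.n_nodes * self.channels_per_node

    @property
    def n_trials(self) -> int:
        return self.n_gestures * self.reps_per_gesture

    @property
    def move_samples(self) -> int:
        return int(round(self.move_s * self.fs))

    @property
    def rest_samples(self) -> int:
        return int(round(self.rest_s * self.fs))

    @property
    def rest_id(self) -> int:
        return self.n_gestures - 1


@dataclass
class GestureSpatialModel:
    """Per-gesture per-channel activation gains plus carrier parameters.

    ``activation[g, c]`` in [0, 1] scales the contraction carrier on channel
    ``c`` during gesture ``g``; the rest gesture (last row) must be all zero.
    ``snr_target_db`` fixes the ON/OFF variance-ratio SNR a gain-1.0 channel
    attains: the carrier amplitude is ``noise_floor_sd * 10**(snr/20)`` so
    that ``10*log10(sigma_on^2/sigma_off^2 - 1)`` equals the target.
    ``node_correlation`` mixes a shared pre-filter component into channels
    of the same node, mimicking the small inter-channel differences seen
    between closely spaced contacts.

    Two sources of trial-to-trial variability emulate why repeated grasps
    are never identical: ``trial_gain_jitter`` is the sigma of a lognormal
    multiplier drawn per trial and channel (contraction-intensity and
    recruitment variability), and ``trial_shift_sd`` is the sigma in
    channels of a rounded Gaussian rotation of the whole activation pattern
    around the ring per trial (slight armband/muscle displacement).  Set
    both to 0 for perfectly repeatable trials.
    """

    activation: np.ndarray
    carrier_band: tuple[float, float] = (30.0, 350.0)
    noise_floor_sd: float = 1.0
    snr_target_db: float = 12.0
    node_correlation: float = 0.6
    trial_gain_jitter: float = 0.25
    trial_shift_sd: float = 0.6

    def __post_init__(self) -> None:
        self.activation = np.asarray(self.activation, dtype=np.float64)
        if self.activation.ndim != 2:
            raise ConfigError("activation must be [n_gestures, n_channels]")
        if not np.isfinite(self.activation).all():
            raise ConfigError("activation gains must be finite")
        if np.any(self.activation[-1] != 0):
            raise ConfigError("rest gesture (last row) must have all-zero gains")
        if self.activation.shape[0] > 1 and np.any(self.activation[:-1].max(axis=1) <= 0):
            raise ConfigError("every non-rest gesture needs at least one active channel")
        if self.noise_floor_sd <= 0:
            raise ConfigError("noise_floor_sd must be positive")
        if not 0 <= self.node_correlation < 1:
            raise ConfigError("node_correlation must be in [0, 1)")

    @property
    def carrier_amplitude(self) -> float:
        return self.noise_floor_sd * 10.0 ** (self.snr_target_db / 20.0)

    @classmethod
    def forearm_default(cls, protocol: ProtocolConfig, bump_width: int = 9,
                        **kwargs) -> "GestureSpatialModel":
        """Overlapping raised-cosine activation bumps rotated around the ring.

        Each non-rest gesture activates a contiguous arc of ``bump_width``
        channels; bump centres are spread evenly around the ring so gestures
        share channels the way neighbouring forearm muscles do.  All bumps
        have identical shape, so gestures differ in *where* the activity
        sits, not in total power -- the discriminative information is spatial.
        """
        n_ch = protocol.n_channels
        n_active = protocol.n_gestures - 1
        act = np.zeros((protocol.n_gestures, n_ch))
        offsets = np.arange(bump_width) - (bump_width - 1) / 2
        bump = 0.5 * (1 + np.cos(np.pi * offsets / ((bump_width + 1) / 2)))
        for g in range(n_active):
            center = int(round(g * n_ch / max(n_active, 1)))
            idx = (center + np.arange(bump_width) - (bump_width - 1) // 2) % n_ch
            act[g, idx] = np.maximum(act[g, idx], bump)
        return cls(activation=act, **kwargs)

    @classmethod
    def uniform(cls, protocol: ProtocolConfig, **kwargs) -> "GestureSpatialModel":
        """All non-rest gestures drive every channel with gain 1 (SNR studies)."""
        act = np.ones((protocol.n_gestures, protocol.n_channels))
        act[-1] = 0.0
        return cls(activation=act, **kwargs)


def generate_trial_schedule(protocol: ProtocolConfig) -> list[tuple[int, int, int]]:
    """Block-randomized trial schedule of movement intervals.

    Returns ``n_gestures * reps_per_gesture`` tuples of
    ``(gesture_id, start_sample, end_sample)`` (half-open), ordered in time.
    Trials are grouped into repetition blocks; within each block every
    gesture appears once in a seed-dependent random order.  Each movement
    interval spans exactly ``move_s * fs`` samples and is followed by
    ``rest_s * fs`` samples of rest before the next trial.
    """
    rng = np.random.default_rng(protocol.seed)
    trial_len = protocol.move_samples + protocol.rest_samples
    schedule = []
    t = 0
    for _ in range(protocol.reps_per_gesture):
        for g in rng.permutation(protocol.n_gestures):
            schedule.append((int(g), t, t + protocol.move_samples))
            t += trial_len
    return schedule


def _correlated_carriers(protocol: ProtocolConfig, spatial: GestureSpatialModel,
                         n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited carriers, correlated within each node."""
    n_ch = protocol.n_channels
    own = rng.standard_normal((n_samples, n_ch))
    r = spatial.node_correlation
    if r > 0:
        shared = rng.standard_normal((n_samples, protocol.n_nodes))
        shared = np.repeat(shared, protocol.channels_per_node, axis=1)
        own = np.sqrt(r) * shared + np.sqrt(1 - r) * own
    low, high = spatial.carrier_band
    sos = sps.butter(4, [low, high], btype="bandpass", fs=protocol.fs, output="sos")
    carriers = sps.sosfiltfilt(sos, own, axis=0)
    carriers /= carriers.std(axis=0, keepdims=True)
    return carriers


def _contraction_envelope(n_samples: int, schedule, protocol: ProtocolConfig) -> np.ndarray:
    """Per-sample 0..1 contraction envelope with raised-cosine ramps."""
    env = np.zeros(n_samples)
    ramp_n = int(round(RAMP_S * protocol.fs))
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
    for _, start, end in schedule:
        env[start:end] = 1.0
        env[start:start + ramp_n] = ramp[: max(0, min(ramp_n, end - start))]
        env[max(start, end - ramp_n):end] = ramp[::-1][: min(ramp_n, end - start)]
    return env


def generate_session(protocol: ProtocolConfig,
                     spatial: GestureSpatialModel | None = None,
                     subject: str = "synthetic-01") -> EmgRecording:
    """Generate one labelled synthetic armband session.

    The session consists of ``n_gestures * reps_per_gesture`` trials, each
    ``move_s`` of gesture-modulated carrier followed by ``rest_s`` of pure
    baseline noise.  Per channel the signal is::

        x[t, c] = noise_floor + A * gain[g(t), c] * envelope(t) * carrier[t, c]

    with ``A`` fixed by ``snr_target_db`` (see :class:`GestureSpatialModel`).
    The label track marks every sample with its gesture id; rest periods and
    the rest gesture's own trials carry the rest id.  Identical
    ``protocol.seed`` yields a bit-identical session.
    """
    if spatial is None:
        spatial = GestureSpatialModel.forearm_default(protocol)
    if spatial.activation.shape != (protocol.n_gestures, protocol.n_channels):
        raise ConfigError(
            f"activation shape {spatial.activation.shape} does not match protocol "
            f"({protocol.n_gestures} gestures, {protocol.n_channels} channels)"
        )
    schedule = generate_trial_schedule(protocol)
    n_samples = protocol.n_trials * (protocol.move_samples + protocol.rest_samples)
    rng = np.random.default_rng(np.random.SeedSequence([protocol.seed, 0xE36]))

    labels = np.full(n_samples, protocol.rest_id, dtype=np.int64)
    gains = np.zeros((n_samples, protocol.n_channels))
    for g, start, end in schedule:
        labels[start:end] = g
        trial_gains = spatial.activation[g]
        if spatial.trial_shift_sd > 0:
            shift = int(round(rng.normal(0.0, spatial.trial_shift_sd)))
            trial_gains = np.roll(trial_gains, shift)
        if spatial.trial_gain_jitter > 0:
            trial_gains = trial_gains * rng.lognormal(
                0.0, spatial.trial_gain_jitter, size=protocol.n_channels)
        gains[start:end] = trial_gains

    carriers = _correlated_carriers(protocol, spatial, n_samples, rng)
    env = _contraction_envelope(n_samples, schedule, protocol)
    noise = rng.standard_normal((n_samples, protocol.n_channels)) * spatial.noise_floor_sd
    data = noise + spatial.carrier_amplitude * gains * env[:, None] * carriers

    return EmgRecording(
        data=data, fs=protocol.fs, labels=labels,
        channel_map=default_channel_map(protocol.n_nodes, protocol.channels_per_node),
        meta={"subject": subject, "session": f"seed-{protocol.seed}",
              "gesture_names": list(GESTURE_NAMES[:protocol.n_gestures])
              if protocol.n_gestures <= len(GESTURE_NAMES)
              else [f"g{i}" for i in range(protocol.n_gestures)],
              "rest_id": protocol.rest_id,
              "schedule": [list(s) for s in schedule]},
    )
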
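"""The in-memory session container and its validation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigError(ValueError):
    """An invalid protocol, filter, detection or model configuration."""


class SchemaError(ValueError):
    """A malformed or inconsistent on-disk session/feature artifact."""


def default_channel_map(n_nodes: int, channels_per_node: int) -> np.ndarray:
    """Channel map for an armband of ``n_nodes`` ring-ordered sensor nodes.

    Returns an integer array of shape ``(n_channels, 2)``; column 0 is the
    node index (0-based) and column 1 the within-node position (1-based,
    1..channels_per_node).  Global channel order is node-major, so channel
    ``3*k + j`` sits at position ``j + 1`` of node ``k`` for a 3-channel node.
    """
    nodes = np.repeat(np.arange(n_nodes), channels_per_node)
    pos = np.tile(np.arange(1, channels_per_node + 1), n_nodes)
    return np.stack([nodes, pos], axis=1).astype(np.int64)


@dataclass
class EmgRecording:
    """A continuous multichannel EMG session with per-sample gesture labels.

    Parameters
    ----------
    data
        Signal array of shape ``(n_samples, n_channels)`` in arbitrary
        amplitude units (uV for real hardware).
    fs
        Sampling rate in Hz.
    labels
        Integer gesture id per sample, shape ``(n_samples,)``.
    channel_map
        ``(n_channels, 2)`` array of (node index, within-node position).
    meta
        Free-form metadata (subject id, session id, processing flags).
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray
    channel_map: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ConfigError(f"data must be 2-D [samples, channels], got shape {self.data.shape}")
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (self.data.shape[0],):
            raise SchemaError(
                f"labels length {self.labels.shape} does not match n_samples {self.data.shape[0]}"
            )
        if not self.fs > 0:
            raise ConfigError(f"sampling rate must be positive, got {self.fs}")
        if np.isnan(self.data).any():
            raise SchemaError("recording contains NaN samples")
        if self.channel_map is not None:
            self.channel_map = np.asarray(self.channel_map, dtype=np.int64)
            if self.channel_map.shape != (self.n_channels, 2):
                raise SchemaError(
                    f"channel_map shape {self.channel_map.shape} does not cover "
                    f"{self.n_channels} channels"
                )
            pairs = {tuple(row) for row in self.channel_map}
            if len(pairs) != self.n_channels:
                raise SchemaError("channel_map entries are not unique")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray, **meta_updates) -> "EmgRecording":
        """Copy of this recording with replaced signal and merged metadata."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return EmgRecording(data=data, fs=self.fs, labels=self.labels.copy(),
                            channel_map=None if self.channel_map is None else self.channel_map.copy(),
                            meta=meta)
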
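"""Filter-chain emulation and overlapping-window segmentation.

The acquisition firmware band-passes each channel with a second-order IIR
Butterworth filter (30-350 Hz) and notches power-line interference
(50/60 Hz).  This module reproduces that chain in software, with a
zero-phase (forward-backward) variant for offline pipelines and a causal
variant for streaming parity.  Windowing follows the overlapping scheme:
281.1 ms windows advanced in 9.3 ms steps, i.e. 300-sample windows with a
10-sample step at 1,067 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .recording import ConfigError, EmgRecording


@dataclass
class FilterSpec:
    band: tuple[float, float] = (30.0, 350.0)
    band_order: int = 2
    notch_hz: float = 50.0
    notch_q: float = 30.0
    fs: float = 1067.0

    def __post_init__(self) -> None:
        low, high = self.band
        if not 0 < low < high < self.fs / 2:
            raise ConfigError(f"band {self.band} infeasible at fs={self.fs}")
        if not 0 < self.notch_hz < self.fs / 2:
            raise ConfigError(f"notch {self.notch_hz} Hz infeasible at fs={self.fs}")


@dataclass
class WindowSpec:
    """Overlapping analysis window geometry, specified in milliseconds.

    Sample counts are derived by rounding ``ms * fs / 1000``; at 1,067 Hz
    the defaults give 300-sample windows with a 10-sample step.
    """

    length_ms: float = 281.1
    step_ms: float = 9.3

    def length_samples(self, fs: float) -> int:
        return int(round(self.length_ms * fs / 1000.0))

    def step_samples(self, fs: float) -> int:
        return int(round(self.step_ms * fs / 1000.0))

    def validate(self, fs: float) -> tuple[int, int]:
        length, step = self.length_samples(fs), self.step_samples(fs)
        if step < 1:
            raise ConfigError(f"step {self.step_ms} ms is below one sample at fs={fs}")
        if length <= step:
            raise ConfigError(f"window length must exceed step ({length} <= {step} samples)")
        return length, step


def apply_filter_chain(rec: EmgRecording, spec: FilterSpec | None = None,
                       zero_phase: bool = True) -> EmgRecording:
    """Band-pass then notch each channel; returns a new recording.

    ``zero_phase=True`` applies each stage forward-backward (no group delay,
    squared magnitude response); ``zero_phase=False`` runs the causal chain
    the acquisition hardware implements.
    """
    if spec is None:
        spec = FilterSpec(fs=rec.fs)
    if abs(spec.fs - rec.fs) > 1e-9:
        raise ConfigError(f"filter fs={spec.fs} does not match recording fs={rec.fs}")
    sos_band = sps.butter(spec.band_order, spec.band, btype="bandpass", fs=rec.fs, output="sos")
    b_notch, a_notch = sps.iirnotch(spec.notch_hz, spec.notch_q, fs=rec.fs)
    sos_notch = sps.tf2sos(b_notch, a_notch)
    sos = np.vstack([sos_band, sos_notch])
    if zero_phase:
        out = sps.sosfiltfilt(sos, rec.data, axis=0)
    else:
        out = sps.sosfilt(sos, rec.data, axis=0)
    return rec.with_data(out, filtered=True, zero_phase=zero_phase,
                         band=list(spec.band), notch_hz=spec.notch_hz)


def window_bounds(n_samples: int, length: int, step: int) -> list[tuple[int, int]]:
    """Half-open (start, end) bounds of the overlapping windows.

    Exactly ``floor((n_samples - length) / step) + 1`` windows, each
    ``length`` samples long, starting at multiples of ``step``.
    """
    if n_samples < length:
        raise ConfigError(f"recording of {n_samples} samples shorter than one {length}-sample window")
    n_win = (n_samples - length) // step + 1
    return [(i * step, i * step + length) for i in range(n_win)]


def segment_windows(rec: EmgRecording, spec: WindowSpec | None = None) -> list[tuple[int, int]]:
    """Window bounds for a recording under the given window spec."""
    spec = spec or WindowSpec()
    length, step = spec.validate(rec.fs)
    return window_bounds(rec.n_samples, length, step)
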
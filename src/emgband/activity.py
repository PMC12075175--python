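"""Double-threshold muscle-activity detection and SNR estimation.

A channel is segmented into alternating ON (active) and OFF (rest) states.
Baseline statistics (mu_n, sigma_n) of the rectified signal fix two
thresholds, LT = mu_n + k1*sigma_n and UT = mu_n + k2*sigma_n with k1 < k2.
A candidate activation is a run of at least ``m`` consecutive rectified
samples above LT that also contains an excursion above UT; shorter
variations of the detector output (in either direction) are rejected.  The
per-channel SNR is computed from the mean ON-state and OFF-state variances
of the raw signal as ``10*log10(sigma_s^2 / sigma_n^2 - 1)`` dB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import ConfigError, EmgRecording

#: minimum number of baseline samples needed for stable threshold estimates
MIN_BASELINE_SAMPLES = 100


@dataclass
class DetectionConfig:
    """Double-threshold detector settings.

    ``k1``/``k2`` scale the lower/upper thresholds above the rectified
    baseline; ``m`` is the minimum run length in samples (about 28 ms at
    1,067 Hz with the default 30); ``baseline_s`` seconds at the start of
    the signal (or of an explicitly supplied baseline interval) estimate
    mu_n, sigma_n.  Because raw surface EMG is zero-mean and crosses zero
    every few samples, thresholding operates on the rectified signal
    smoothed by a ``smooth_ms`` moving average (the activity envelope);
    ``smooth_ms=0`` thresholds the bare rectified samples.
    """

    k1: float = 3.0
    k2: float = 5.0
    m: int = 30
    baseline_s: float = 1.0
    smooth_ms: float = 25.0

    def __post_init__(self) -> None:
        if not self.k1 < self.k2:
            raise ConfigError(f"need k1 < k2, got k1={self.k1}, k2={self.k2}")
        if self.m < 1:
            raise ConfigError("m must be >= 1")
        if self.baseline_s <= 0:
            raise ConfigError("baseline_s must be positive")
        if self.smooth_ms < 0:
            raise ConfigError("smooth_ms must be >= 0")


@dataclass
class ActivitySegmentation:
    """Alternating ON/OFF states of one channel plus threshold statistics."""

    states: list  # ordered (state: 'ON'|'OFF', start, end), half-open, tiling the span
    on_variances: np.ndarray
    off_variances: np.ndarray
    mu_n: float
    sigma_n: float
    lt: float
    ut: float

    @property
    def n_on(self) -> int:
        return len(self.on_variances)

    @property
    def n_off(self) -> int:
        return len(self.off_variances)

    @property
    def e_n(self) -> float:
        """Baseline noise level: mean OFF-state standard deviation."""
        if self.n_off == 0:
            return float("nan")
        return float(np.mean(np.sqrt(self.off_variances)))

    def on_intervals(self) -> list[tuple[int, int]]:
        return [(s, e) for kind, s, e in self.states if kind == "ON"]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, end) runs of True in a boolean array."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_on_off(x: np.ndarray, cfg: DetectionConfig | None = None,
                  fs: float = 1067.0,
                  baseline: tuple[int, int] | None = None) -> ActivitySegmentation:
    """Segment a single-channel signal into ON/OFF states.

    The signal is rectified (absolute value) and smoothed into an envelope
    internally; the first ``cfg.baseline_s`` seconds (or the explicit
    ``baseline`` (start, end) sample interval, e.g. a known rest period)
    provide mu_n, sigma_n.  State variances are computed on the raw
    (unrectified) segments.
    """
    cfg = cfg or DetectionConfig()
    x = np.asarray(x, dtype=np.float64).ravel()
    if baseline is None:
        baseline = (0, int(round(cfg.baseline_s * fs)))
    b0, b1 = baseline
    n_base = b1 - b0
    if n_base < MIN_BASELINE_SAMPLES or b0 < 0 or b1 > x.size:
        raise ConfigError(
            f"baseline interval {baseline} invalid (need >= {MIN_BASELINE_SAMPLES} "
            f"samples within the {x.size}-sample signal)"
        )
    # remove any DC offset (estimated on the baseline) before rectification,
    # so detection depends only on signal fluctuations
    r = np.abs(x - x[b0:b1].mean())
    n_smooth = int(round(cfg.smooth_ms * fs / 1000.0))
    if n_smooth > 1:
        kernel = np.ones(n_smooth) / n_smooth
        r = np.convolve(r, kernel, mode="same")
    mu_n = float(r[b0:b1].mean())
    sigma_n = float(r[b0:b1].std())
    if sigma_n == 0:
        raise ConfigError("zero-variance baseline segment")
    lt = mu_n + cfg.k1 * sigma_n
    ut = mu_n + cfg.k2 * sigma_n

    detector = np.zeros(x.size, dtype=bool)
    for start, end in _runs(r > lt):
        if end - start >= cfg.m and r[start:end].max() > ut:
            detector[start:end] = True
    # reject OFF gaps shorter than m between accepted activations
    for start, end in _runs(~detector):
        if start > 0 and end < x.size and end - start < cfg.m:
            detector[start:end] = True

    states = []
    on_var, off_var = [], []
    pos = 0
    for start, end in _runs(detector):
        if start > pos:
            states.append(("OFF", pos, start))
            off_var.append(x[pos:start].var())
        states.append(("ON", start, end))
        on_var.append(x[start:end].var())
        pos = end
    if pos < x.size:
        states.append(("OFF", pos, x.size))
        off_var.append(x[pos:].var())

    return ActivitySegmentation(states=states, on_variances=np.array(on_var),
                                off_variances=np.array(off_var),
                                mu_n=mu_n, sigma_n=sigma_n, lt=lt, ut=ut)


def compute_snr(seg: ActivitySegmentation) -> float:
    """SNR in dB from mean ON and OFF state variances.

    ``10*log10(sigma_s^2 / sigma_n^2 - 1)``; returns ``-inf`` (flagged
    degenerate, not an exception) when the ON variance does not exceed the
    OFF variance, and ``nan`` when either state is absent.
    """
    if seg.n_on == 0 or seg.n_off == 0:
        return float("nan")
    sigma_s2 = float(np.mean(seg.on_variances))
    sigma_n2 = float(np.mean(seg.off_variances))
    if sigma_n2 <= 0 or sigma_s2 <= sigma_n2:
        return float("-inf")
    return 10.0 * np.log10(sigma_s2 / sigma_n2 - 1.0)


def snr_report(rec: EmgRecording, cfg: DetectionConfig | None = None) -> pd.DataFrame:
    """Average SNR per channel over a whole recording.

    Runs the double-threshold detector independently on every channel and
    reports one SNR value per channel, with the ON/OFF state counts and the
    baseline noise level e_n.  When the recording carries a label track,
    the first sufficiently long rest-labelled run (rest = the highest
    gesture id) serves as the baseline segment; otherwise the first
    ``baseline_s`` seconds are assumed rest.  Channels where detection or
    the SNR is degenerate carry NaN/-inf entries rather than raising.
    """
    cfg = cfg or DetectionConfig()
    baseline = None
    if rec.labels.size and rec.labels.min() != rec.labels.max():
        rest_id = int(rec.meta.get("rest_id", rec.labels.max()))
        need = max(MIN_BASELINE_SAMPLES, int(round(cfg.baseline_s * rec.fs)))
        for start, end in _runs(rec.labels == rest_id):
            if end - start >= need:
                baseline = (int(start), int(start + need))
                break
    rows = []
    for c in range(rec.n_channels):
        try:
            seg = detect_on_off(rec.data[:, c], cfg, fs=rec.fs, baseline=baseline)
            rows.append({"channel": c, "snr_db": compute_snr(seg),
                         "n_on": seg.n_on, "n_off": seg.n_off, "e_n": seg.e_n})
        except ConfigError:
            rows.append({"channel": c, "snr_db": float("nan"), "n_on": 0, "n_off": 0,
                         "e_n": float("nan")})
    return pd.DataFrame(rows)
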
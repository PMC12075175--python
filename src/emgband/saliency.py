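"""Gradient saliency maps over the [time_steps, channels] plane.

The importance of each spatio-temporal "pixel" (one channel at one time
step) for a gesture class c is scored by the magnitude of the gradient of
the class score S_c with respect to the input tensor, evaluated at a given
sample -- the first-order Taylor view of the decoder: near the sample,
S_c(I) ~ w^T i + b with w = dS_c/dI, so |w| ranks input components.  The
class score is the pre-softmax logit (softmax saturation would flatten the
maps).  Raw scores have shape [time_steps, channels, features]; averaging
over the feature axis gives the per-gesture map [time_steps, channels]
(e.g. [60, 21] for the default configuration).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .models import TrainedDecoder
from .recording import ConfigError


@dataclass
class SaliencyMap:
    """Non-negative [time_steps, channels] importance scores for one gesture."""

    scores: np.ndarray
    gesture: int
    aggregation: str = "single-sample"  # | mean-over-samples | mean-over-subjects

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 2:
            raise ConfigError("saliency scores must be [time_steps, channels]")
        if (self.scores < 0).any():
            raise ConfigError("saliency scores must be non-negative")

    @property
    def shape(self) -> tuple:
        return self.scores.shape

    def channel_importance(self) -> np.ndarray:
        """Mean score per channel (collapses the time axis)."""
        return self.scores.mean(axis=0)


def saliency_single(decoder: TrainedDecoder, sample: np.ndarray, gesture: int) -> np.ndarray:
    """Raw |dS_c/dI| score array [time_steps, channels, features] at one sample."""
    if decoder.kind == "lda":
        raise ConfigError("gradient saliency needs a differentiable decoder (tcn/stcn); "
                          "use lda_weight_map for the linear baseline")
    class_idx = int(np.searchsorted(decoder.classes, gesture))
    if class_idx >= decoder.classes.size or decoder.classes[class_idx] != gesture:
        raise ConfigError(f"gesture {gesture} not in decoder classes {decoder.classes}")
    grad = decoder.input_gradient(sample, class_idx)
    if decoder.kind == "tcn" and grad.shape != sample.shape:
        grad = grad.reshape(sample.shape)
    return np.abs(grad)


def lda_weight_map(decoder: TrainedDecoder, gesture: int,
                   shape: tuple[int, int]) -> SaliencyMap:
    """|w| of the linear discriminant for one class, tiled over time steps."""
    if decoder.kind != "lda":
        raise ConfigError("lda_weight_map applies to the LDA decoder only")
    class_idx = int(np.searchsorted(decoder.classes, gesture))
    w = np.abs(decoder.model.coef_[class_idx]).reshape(shape[1], -1).mean(axis=1)
    return SaliencyMap(scores=np.tile(w, (shape[0], 1)), gesture=gesture)


def average_features(raw: np.ndarray, gesture: int = -1) -> SaliencyMap:
    """Mean over the feature axis: [T, C, F] raw scores -> [T, C] map."""
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 3:
        raise ConfigError("raw saliency must be [time_steps, channels, features]")
    if not np.isfinite(raw).all():
        raise ConfigError("raw saliency contains non-finite values")
    return SaliencyMap(scores=np.abs(raw).mean(axis=2), gesture=gesture,
                       aggregation="single-sample")


def aggregate_maps(maps: list[SaliencyMap], level: str = "samples") -> SaliencyMap:
    """Elementwise mean of homogeneous maps (across samples or subjects)."""
    if not maps:
        raise ConfigError("no maps to aggregate")
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise ConfigError(f"heterogeneous map shapes {shapes}")
    agg = "mean-over-subjects" if level == "subjects" else "mean-over-samples"
    return SaliencyMap(scores=np.mean([m.scores for m in maps], axis=0),
                       gesture=maps[0].gesture, aggregation=agg)


def saliency_for_gesture(decoder: TrainedDecoder, tensor: np.ndarray,
                         labels: np.ndarray, gesture: int,
                         correct_only: bool = True) -> SaliencyMap:
    """Per-gesture map averaged over (by default correctly classified) samples."""
    idx = np.flatnonzero(labels == gesture)
    if idx.size == 0:
        raise ConfigError(f"no samples labelled {gesture}")
    if correct_only:
        preds = decoder.predict(tensor[idx])
        keep = idx[preds == gesture]
        idx = keep if keep.size else idx  # fall back to all samples of the class
    maps = [average_features(saliency_single(decoder, tensor[i], gesture), gesture)
            for i in idx]
    return aggregate_maps(maps, level="samples")


def export_heatmap(smap: SaliencyMap, csv_path: str | Path,
                   png_path: str | Path | None = None) -> None:
    """Write a map as CSV (time steps x channels) and optionally a PNG heatmap."""
    np.savetxt(csv_path, smap.scores, delimiter=",")
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 4))
        im = ax.imshow(smap.scores.T, aspect="auto", origin="lower", cmap="viridis")
        ax.set_xlabel("time step")
        ax.set_ylabel("channel")
        ax.set_title(f"gesture {smap.gesture} ({smap.aggregation})")
        fig.colorbar(im, ax=ax, label="|dS/dI|")
        fig.savefig(png_path, dpi=120, bbox_inches="tight")
        plt.close(fig)
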
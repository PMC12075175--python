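"""The three gesture decoders and their training loop.

* ``fit_lda`` -- shrinkage-regularized linear discriminant analysis on
  per-window feature vectors, with majority voting across a sample's
  time steps at prediction time (the classical myocontrol baseline).
* ``build_vanilla_tcn`` -- causal dilated temporal convolutions only; by
  default the channel and feature axes are stacked into one feature axis
  (the standard stacked-TCN formulation).  A per-channel-independent mode
  (shared weights across channels, no cross-channel mixing) is available
  for matched-capacity comparisons.
* ``build_stcn`` -- the simultaneous spatio-temporal network: every block
  convolves its input both backward in time (causal, dilated) and across
  the electrode ring (circular) in parallel, merges the branches, and
  applies batch normalisation, ReLU and dropout.

Training uses Adam on cross-entropy with early stopping on a validation
split; everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from . import nn
from .features import FeatureStandardizer, WindowedFeatures
from .recording import ConfigError


@dataclass
class StcnConfig:
    n_blocks: int = 3
    temporal_kernel: int = 3
    dilations: tuple = (1, 2, 4)
    spatial_kernel: int = 3
    filters: int = 32
    dropout_p: float = 0.3
    merge: str = "concat"
    classes: tuple | None = None

    def __post_init__(self) -> None:
        if len(self.dilations) != self.n_blocks:
            raise ConfigError("need one dilation per block")
        if any(d < 1 for d in self.dilations):
            raise ConfigError("dilations must be positive")
        if not 0 <= self.dropout_p < 1:
            raise ConfigError("dropout_p must be in [0, 1)")


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    lr: float = 1e-3
    patience: int = 10
    val_fraction: float = 0.15
    seed: int = 0


def build_stcn(cfg: StcnConfig, input_shape: tuple[int, int, int],
               seed: int = 0) -> nn.SequenceNet:
    """Untrained simultaneous spatio-temporal network for [T, C, F] inputs."""
    T, C, F = input_shape
    if cfg.spatial_kernel > C > 1:
        raise ConfigError(f"spatial_kernel {cfg.spatial_kernel} exceeds {C} channels")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x57C]))
    layers: list[nn.Layer] = []
    f_in = F
    for i in range(cfg.n_blocks):
        block = nn.ParallelConvBlock(
            temporal=nn.CausalTemporalConv(f_in, cfg.filters, cfg.temporal_kernel,
                                           cfg.dilations[i], rng),
            spatial=nn.CircularSpatialConv(f_in, cfg.filters,
                                           min(cfg.spatial_kernel, C), rng),
            merge=cfg.merge,
        )
        f_in = 2 * cfg.filters if cfg.merge == "concat" else cfg.filters
        layers += [block, nn.BatchNorm(f_in), nn.ReLU(), nn.Dropout(cfg.dropout_p)]
    n_classes = len(cfg.classes) if cfg.classes else 6
    return nn.SequenceNet(layers, nn.TimePoolDense(C, f_in, n_classes, rng))


def build_vanilla_tcn(cfg: StcnConfig, input_shape: tuple[int, int, int],
                      channel_mode: str = "flatten", seed: int = 0) -> nn.SequenceNet:
    """Untrained vanilla TCN (temporal convolutions only, no spatial branch).

    ``channel_mode='flatten'`` stacks channels x features into the feature
    axis; ``'independent'`` keeps channels separate with weights shared
    across them (a capacity-matched temporal-only counterpart to the stcn).
    """
    T, C, F = input_shape
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7C2]))
    layers: list[nn.Layer] = []
    if channel_mode == "flatten":
        layers.append(nn.FlattenChannels())
        f_in = C * F
    elif channel_mode == "independent":
        f_in = F
    else:
        raise ConfigError(f"channel_mode must be 'flatten' or 'independent', got '{channel_mode}'")
    for i in range(cfg.n_blocks):
        block = nn.ParallelConvBlock(
            temporal=nn.CausalTemporalConv(f_in, cfg.filters, cfg.temporal_kernel,
                                           cfg.dilations[i], rng),
            spatial=None,
        )
        f_in = cfg.filters
        layers += [block, nn.BatchNorm(f_in), nn.ReLU(), nn.Dropout(cfg.dropout_p)]
    n_classes = len(cfg.classes) if cfg.classes else 6
    return nn.SequenceNet(layers, nn.TimePoolDense(C if channel_mode == "independent" else 1, f_in, n_classes, rng))


@dataclass
class TrainedDecoder:
    """A fitted decoder with its preprocessing statistics and class list."""

    kind: str  # 'lda' | 'tcn' | 'stcn'
    model: object
    standardizer: FeatureStandardizer
    classes: np.ndarray
    history: dict = field(default_factory=dict)

    def predict_proba(self, tensor: np.ndarray) -> np.ndarray:
        """Class probabilities per sample; rows sum to 1."""
        z = self.standardizer.transform(tensor)
        if self.kind == "lda":
            B, T, C, F = z.shape
            flat = z.reshape(B * T, C * F)
            p = self.model.predict_proba(flat).reshape(B, T, -1)
            return p.mean(axis=1)
        return nn.softmax(self.model.forward(z, train=False))

    def predict(self, tensor: np.ndarray) -> np.ndarray:
        z = self.standardizer.transform(tensor)
        if self.kind == "lda":
            B, T, C, F = z.shape
            win_pred = self.model.predict(z.reshape(B * T, C * F)).reshape(B, T)
            voted = []
            for row in win_pred:
                vals, counts = np.unique(row, return_counts=True)
                voted.append(vals[np.argmax(counts)])
            return self.classes[np.asarray(voted, dtype=int)]
        probs = nn.softmax(self.model.forward(z, train=False))
        return self.classes[np.argmax(probs, axis=1)]

    def accuracy(self, tensor: np.ndarray, labels: np.ndarray) -> float:
        return float(np.mean(self.predict(tensor) == labels))

    def input_gradient(self, sample: np.ndarray, class_idx: int) -> np.ndarray:
        if self.kind == "lda":
            raise ConfigError("gradient saliency is undefined for the LDA decoder")
        z = self.standardizer.transform(sample[None])
        return self.model.input_gradient(z, class_idx)[0]


def fit_lda(feats: WindowedFeatures | np.ndarray, labels: np.ndarray | None = None) -> TrainedDecoder:
    """Shrinkage-regularized LDA on flattened per-window feature vectors.

    Every time step of a sample contributes one training row (channels x
    features flattened) carrying the sample's label; prediction majority-
    votes the per-window decisions over a sample's time steps.
    """
    if isinstance(feats, WindowedFeatures):
        tensor, labels = feats.tensor, feats.labels
    else:
        tensor = feats
    classes = np.unique(labels)
    if classes.size < 2:
        raise ConfigError("LDA needs at least two classes")
    std = FeatureStandardizer().fit(tensor)
    z = std.transform(tensor)
    B, T, C, F = z.shape
    rows = z.reshape(B * T, C * F)
    row_labels = np.searchsorted(classes, np.repeat(labels, T))
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lda.fit(rows, row_labels)
    return TrainedDecoder(kind="lda", model=lda, standardizer=std, classes=classes)


def train(model: nn.SequenceNet, feats: WindowedFeatures | np.ndarray,
          labels: np.ndarray | None = None, cfg: TrainConfig | None = None,
          kind: str = "stcn") -> TrainedDecoder:
    """Train a network decoder with Adam, early-stopping on validation loss.

    Standardization statistics are computed on the training portion only
    (after the validation split) and stored with the decoder.  A fixed
    ``cfg.seed`` makes the split, shuffling, dropout and hence the final
    weights bit-reproducible.  A NaN loss aborts with diagnostics.
    """
    cfg = cfg or TrainConfig()
    if isinstance(feats, WindowedFeatures):
        tensor, labels = feats.tensor, feats.labels
    else:
        tensor = feats
    classes = np.unique(labels)
    y = np.searchsorted(classes, labels)
    n = tensor.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7124]))
    order = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n))) if cfg.val_fraction > 0 and n >= 8 else 0
    val_idx, tr_idx = order[:n_val], order[n_val:]

    std = FeatureStandardizer().fit(tensor[tr_idx])
    Xtr, ytr = std.transform(tensor[tr_idx]), y[tr_idx]
    Xval, yval = std.transform(tensor[val_idx]), y[val_idx]

    opt = nn.Adam(model, lr=cfg.lr)
    best_loss, best_state, best_epoch, stale = np.inf, model.get_state(), 0, 0
    history = {"train_loss": [], "val_loss": []}
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(tr_idx))
        ep_loss, n_batches = 0.0, 0
        for start in range(0, len(perm), cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            model.zero_grads()
            logits = model.forward(Xtr[idx], train=True, rng=rng)
            loss, dlogits = nn.cross_entropy_grad(logits, ytr[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch {start // cfg.batch_size}; "
                    f"lr={cfg.lr}, batch_size={cfg.batch_size}"
                )
            model.backward(dlogits)
            opt.step()
            ep_loss += loss
            n_batches += 1
        history["train_loss"].append(ep_loss / max(n_batches, 1))

        if n_val:
            vlogits = model.forward(Xval, train=False)
            vloss, _ = nn.cross_entropy_grad(vlogits, yval)
        else:
            vloss = history["train_loss"][-1]
        history["val_loss"].append(vloss)
        if vloss < best_loss - 1e-6:
            best_loss, best_state, best_epoch, stale = vloss, model.get_state(), epoch, 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    model.set_state(best_state)
    history["best_epoch"] = best_epoch
    return TrainedDecoder(kind=kind, model=model, standardizer=std,
                          classes=classes, history=history)
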
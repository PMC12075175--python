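"""Pre-packaged synthetic studies: channel recovery and the density comparison.

These runners reproduce the two headline analyses on synthetic subjects:

* :func:`channel_recovery_study` — does gradient saliency of a trained
  spatio-temporal network rank the truly active channels (known from the
  generator's activation gains) above the silent ones?
* :func:`density_decoder_study` — per-subject decoding accuracy for the
  medium- (21-channel) and low-density (7 middle channels) configurations
  and for the spatio-temporal network vs the vanilla TCN.

Both run at a reduced scale (repetitions per gesture, network width and
training epochs) chosen so a full study completes on a single CPU in
minutes; the protocol geometry (21 channels, 1,067 Hz, 6 s movement +
6 s rest, six classes, 300/10-sample windows, 60 time steps) is never
reduced.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import cross_validate
from .features import extract_feature_tensor
from .io import select_density
from .models import StcnConfig, TrainConfig, build_stcn, train
from .preprocess import apply_filter_chain
from .saliency import saliency_for_gesture
from .synthetic import GestureSpatialModel, ProtocolConfig, generate_session

REDUCED_REPS = 2          # repetitions per gesture for desk-scale studies
STUDY_FILTERS = 8         # network width used by the studies
STUDY_EPOCHS = 12


def _study_seed(base: int, *branch: int) -> int:
    return int(np.random.SeedSequence([base, *branch]).generate_state(1)[0] % (2 ** 31))


def _subject_features(seed: int, density: str = "medium"):
    protocol = ProtocolConfig(reps_per_gesture=REDUCED_REPS, seed=seed)
    spatial = GestureSpatialModel.forearm_default(protocol)
    rec = apply_filter_chain(generate_session(protocol, spatial))
    return extract_feature_tensor(select_density(rec, density)), protocol, spatial


def channel_recovery_study(n_seeds: int = 10, base_seed: int = 0) -> pd.DataFrame:
    """Saliency channel scores vs generator ground truth over repeated runs.

    For each seed a fresh synthetic subject is generated, a spatio-temporal
    network is trained on it, and per-gesture saliency maps are reduced to
    mean channel importances.  Returns one row per (seed, gesture, channel)
    with the importance score and whether the channel is truly active
    (activation gain >= 0.5) for that gesture.
    """
    rows = []
    for i in range(n_seeds):
        seed = _study_seed(base_seed, 0xA11, i)
        feats, protocol, spatial = _subject_features(seed)
        cfg = StcnConfig(filters=STUDY_FILTERS, classes=tuple(np.unique(feats.labels)))
        net = build_stcn(cfg, feats.tensor.shape[1:], seed=seed)
        dec = train(net, feats, cfg=TrainConfig(epochs=STUDY_EPOCHS,
                                                patience=STUDY_EPOCHS, seed=seed),
                    kind="stcn")
        for g in range(protocol.n_gestures - 1):
            smap = saliency_for_gesture(dec, feats.tensor, feats.labels, g)
            imp = smap.channel_importance()
            for c in range(protocol.n_channels):
                rows.append({"seed": i, "gesture": g, "channel": c,
                             "importance": float(imp[c]),
                             "active": bool(spatial.activation[g, c] >= 0.5)})
    return pd.DataFrame(rows)


def density_decoder_study(n_subjects: int = 10, base_seed: int = 0,
                          decoders: tuple = ("stcn", "tcn"),
                          n_splits: int = 2) -> pd.DataFrame:
    """Per-subject cross-validated accuracy per decoder per density.

    Each synthetic subject gets its own session seed; every decoder sees
    the identical feature tensors, and the low-density condition is the
    exact 7-middle-channel subset of the medium-density recording, so the
    comparisons are fully paired.
    """
    rows = []
    for s in range(n_subjects):
        seed = _study_seed(base_seed, 0xDE2, s)
        for density in ("medium", "low"):
            feats, _, _ = _subject_features(seed, density)
            for kind in decoders:
                acc = cross_validate(
                    feats, kind, n_splits=n_splits,
                    model_cfg=StcnConfig(filters=STUDY_FILTERS),
                    train_cfg=TrainConfig(epochs=STUDY_EPOCHS, patience=STUDY_EPOCHS),
                    seed=seed)
                rows.append({"subject": s, "decoder": kind, "density": density,
                             "accuracy": acc})
    return pd.DataFrame(rows)
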
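import numpy as np
import pytest

import emgband as eb
from emgband.models import StcnConfig, TrainConfig, build_stcn, train


@pytest.fixture(scope="session")
def small_protocol():
    return eb.ProtocolConfig(reps_per_gesture=2, seed=1)


@pytest.fixture(scope="session")
def small_session(small_protocol):
    return eb.generate_session(small_protocol)


@pytest.fixture(scope="session")
def filtered_session(small_session):
    return eb.apply_filter_chain(small_session)


@pytest.fixture(scope="session")
def feats_medium(filtered_session):
    return eb.extract_feature_tensor(filtered_session)


@pytest.fixture(scope="session")
def trained_stcn(feats_medium):
    """One small spatio-temporal network fitted on the shared session."""
    cfg = StcnConfig(filters=8, classes=tuple(np.unique(feats_medium.labels)))
    net = build_stcn(cfg, feats_medium.tensor.shape[1:], seed=0)
    return train(net, feats_medium, cfg=TrainConfig(epochs=12, patience=12, seed=0),
                 kind="stcn")
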
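import numpy as np
import pytest

from poredelay.cnn import CnnSpec, TrainConfig, train
from poredelay.images import render_dataset
from poredelay.sim import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def sim_cfg():
    return SimConfig()


@pytest.fixture(scope="session")
def small_events(sim_cfg):
    """Mixed labeled events reused by feature/rule tests."""
    return generate_dataset(sim_cfg, 30, 30, seed=101)


@pytest.fixture(scope="session")
def trained_model_28(sim_cfg):
    """A small but competent model at 28x28, shared across CNN tests."""
    train_ev = generate_dataset(sim_cfg, 150, 150, seed=201)
    val_ev = generate_dataset(sim_cfg, 50, 50, seed=202)
    xtr, _ = render_dataset(train_ev, 28)
    xva, _ = render_dataset(val_ev, 28)
    model = train(
        xtr,
        [e.label for e in train_ev],
        xva,
        [e.label for e in val_ev],
        CnnSpec(input_resolution=28),
        TrainConfig(epochs_max=6, seed=5),
    )
    return model


@pytest.fixture(scope="session")
def blind_events_small(sim_cfg):
    return generate_dataset(sim_cfg, 80, 80, seed=203)
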
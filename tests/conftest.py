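import numpy as np
import pytest

from ndlsdti import DTIModel, EncoderConfig, PlantedWorld, generate_world

#: Cheap stage settings for smoke/property tests (not the study defaults).
FAST_ENCODER = dict(epochs=6, hidden_dim=32, output_dim=32)
FAST_GBDT = {"n_estimators": 40, "max_bin": 63}


@pytest.fixture(scope="session")
def tiny_world():
    """A 24-drug x 16-target planted world with clear signal."""
    world = PlantedWorld(n_drugs=24, n_targets=16, n_clusters=4,
                         p_in=0.8, p_out=0.05, seed=11)
    drugs, targets, pairs = generate_world(world)
    return world, drugs, targets, pairs


@pytest.fixture()
def tiny_model(tiny_world):
    _, drugs, targets, pairs = tiny_world
    return DTIModel(drugs, targets, pairs, seed=11,
                    encoder_config=EncoderConfig(**FAST_ENCODER),
                    gbdt_params=dict(FAST_GBDT))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
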
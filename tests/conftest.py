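import numpy as np
import pytest

import spatsim as ss

#: epochs used for every trained model in the suite — enough for the
#: 300-cell fixture to separate populations without dominating runtime
TRAIN_EPOCHS = 100


@pytest.fixture(scope="session")
def nb_fixture() -> ss.ExpressionDataset:
    """The standard negative-binomial fixture: 3 populations x 100 cells,
    100 genes, planted marker blocks."""
    return ss.generate_fixture_scrnaseq(ss.FixtureConfig(seed=1))


@pytest.fixture(scope="session")
def trained_model(nb_fixture) -> ss.TrainedModel:
    """One VAE trained on the fixture, shared across the suite."""
    return ss.train_vae(nb_fixture, ss.VAEConfig(epochs=TRAIN_EPOCHS, seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
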
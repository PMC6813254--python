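import numpy as np
import pytest

from inoviscope.pipeline import default_training_config, detect_all, train_from_fixture
from inoviscope.synthetic_data import SimulationConfig, generate_fixture, seed_pi_model


@pytest.fixture(scope="session")
def benchmark_fixture():
    """The 50-genome benchmark: 25 planted proviruses, 25 hard negatives."""
    return generate_fixture(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def trained_model():
    """Window classifier trained on an independent synthetic fixture."""
    genomes, truth = generate_fixture(default_training_config())
    return train_from_fixture(genomes, truth, seed=42, n_trees=2000)


@pytest.fixture(scope="session")
def benchmark_predictions(benchmark_fixture, trained_model):
    genomes, truth = benchmark_fixture
    predictions, owner = detect_all(genomes, trained_model, [seed_pi_model()])
    return predictions, owner


@pytest.fixture(scope="session")
def small_fixture():
    """A 6-genome fixture for cheap unit tests."""
    cfg = SimulationConfig(
        seed=11, n_genomes=6, n_inovirus=3,
        n_plasmid_confounders=2, n_caudovirales_confounders=1,
    )
    return generate_fixture(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
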
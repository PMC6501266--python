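import numpy as np
import pytest

from eegdecode import (HyperGrid, HyperParams, SimulationConfig, fit,
                       generate_dataset, prepare_features)


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced paradigm: 6 subjects, 23 categories x 6 trials, full montage."""
    return SimulationConfig(n_subjects=6, trials_per_category=6, rng_seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """No planted class effect: animate and inanimate trials share one process."""
    return generate_dataset(
        SimulationConfig(n_subjects=6, trials_per_category=6,
                         effect_amplitude=0.0, rng_seed=11))


@pytest.fixture(scope="session")
def tiny_grid():
    return HyperGrid(np.geomspace(0.25, 15, 3), np.geomspace(5e-7, 2.5e-2, 3))


@pytest.fixture(scope="session")
def pseudo_features(small_dataset):
    return prepare_features(small_dataset, "pseudotrial")


@pytest.fixture(scope="session")
def pseudo_model(pseudo_features):
    return fit(pseudo_features, HyperParams(c=2.0, gamma=3e-4))
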
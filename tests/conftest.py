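import numpy as np
import pytest

from befstress.design import build_design
from befstress.synthetic import SyntheticConfig, gen_dataset, gen_ground_truth


@pytest.fixture(scope="session")
def tiny_truth_design():
    """2-species ground truth (no interactions) with monocultures + the pair."""
    cfg = SyntheticConfig(n_species=2, seed=42, generating_scenario="S1")
    return gen_ground_truth(cfg, assemblage_counts={1: 2, 2: 1})


@pytest.fixture(scope="session")
def tiny_dataset(tiny_truth_design):
    truth, design = tiny_truth_design
    data = gen_dataset(truth, design, noise_cv=0.0, seed=42)
    return truth, design, data


@pytest.fixture(scope="session")
def small_design():
    """8-species design with monocultures and a few mixtures."""
    return build_design(seed=3, assemblage_counts={1: 8, 2: 3, 4: 3})


@pytest.fixture(scope="session")
def small_noisy(small_design):
    """8-species S4 truth + noisy dataset on the small design."""
    cfg = SyntheticConfig(seed=9, generating_scenario="S4")
    truth, design = gen_ground_truth(cfg, design=small_design)
    data = gen_dataset(truth, design, noise_cv=0.05, seed=9)
    return truth, design, data


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
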
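import numpy as np
import pandas as pd
import pytest

import plp


@pytest.fixture(scope="session")
def chain_network():
    return plp.generate_toy_network("chain", 3)


@pytest.fixture(scope="session")
def diamond_network():
    return plp.generate_toy_network("diamond")


@pytest.fixture(scope="session")
def candidate_modes():
    """The default 200-mode candidate dictionary used across tests."""
    return plp.random_modes(200, seed=1)


@pytest.fixture(scope="session")
def small_modes():
    return plp.random_modes(40, seed=5)


@pytest.fixture(scope="session")
def default_dataset(candidate_modes):
    """One default-condition dataset (134 obs, 26 envirome vars, 3 active)."""
    X, R, truth = plp.generate_dataset(candidate_modes, plp.GeneratorSpec(seed=0))
    return X, R, truth


@pytest.fixture(scope="session")
def fitted_model(candidate_modes, default_dataset):
    X, R, _ = default_dataset
    return plp.select_efms(X, R, candidate_modes)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_table(rng):
    values = rng.normal(size=(10, 5))
    return pd.DataFrame(
        values,
        index=[f"obs{i}" for i in range(10)],
        columns=[f"var{j}" for j in range(5)],
    )
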
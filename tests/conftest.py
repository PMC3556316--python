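import numpy as np
import pandas as pd
import pytest

from gamcokrige.synthetic import SyntheticConfig, default_config, make_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_bundle():
    """One default-configuration study region (n=326), shared across tests."""
    return make_dataset(default_config(seed=42))


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced region (n=80) for tests where scale is irrelevant."""
    return make_dataset(default_config(seed=7, n_sites=80))


@pytest.fixture()
def scattered_coords(rng):
    return rng.uniform([0.0, 0.0], [50_000.0, 45_000.0], (326, 2))
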
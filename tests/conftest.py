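from datetime import date

import numpy as np
import pytest

from ckdcdss import GeneratorConfig, generate_population


@pytest.fixture(scope="session")
def config():
    return GeneratorConfig(seed=1, n_providers=20, mean_panel_size=10)


@pytest.fixture(scope="session")
def ehr(config):
    return generate_population(config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def index_date(config):
    return config.index_date
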
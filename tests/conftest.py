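import numpy as np
import pytest

from chequity import CheFlagger, GeneratorConfig, generate_panel


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_households=400, seed=1)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return generate_panel(small_config)


@pytest.fixture(scope="session")
def flagged_panel(small_panel):
    return CheFlagger().fit_transform(small_panel.frame)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
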
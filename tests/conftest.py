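import numpy as np
import pytest

from driftrace import ddm_core
from driftrace.synthetic_data import GeneratorConfig


@pytest.fixture(scope="session")
def arbitrary_easy():
    return ddm_core.best_fit_condition("arbitrary", "easy")


@pytest.fixture(scope="session")
def deliberate_easy():
    return ddm_core.best_fit_condition("deliberate", "easy")


@pytest.fixture
def small_gen_cfg():
    """A small but structurally complete generator configuration."""
    return GeneratorConfig(n_subjects=2, trials_per_condition=15)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
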
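import numpy as np
import pytest

from psmiss.missingness import impose_mcar
from psmiss.synthetic_data import GeneratorConfig, generate_complete_sample


@pytest.fixture
def rng():
    return np.random.default_rng(20210)


@pytest.fixture(scope="session")
def sample_a():
    """A moderate scenario-A sample shared across read-only tests."""
    return generate_complete_sample(GeneratorConfig(n=600, scenario="A", seed=11))


@pytest.fixture(scope="session")
def incomplete_a(sample_a):
    """sample_a with 25% MCAR missingness on the confounders."""
    return impose_mcar(sample_a, 0.25, np.random.default_rng(12))
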
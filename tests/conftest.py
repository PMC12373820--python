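import numpy as np
import pytest

from ctdose.config import GeneratorConfig
from ctdose.simulate import generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort reused by read-only tests."""
    return generate_cohort(GeneratorConfig(n_participants=800, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
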
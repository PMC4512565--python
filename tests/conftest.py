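import numpy as np
import pytest

from mammotriage.phantom import PhantomParams, generate_subject
from mammotriage.registration import RegistrationConfig


@pytest.fixture(scope="session")
def fast_reg_config() -> RegistrationConfig:
    """Cheap registration settings for small test images."""
    return RegistrationConfig(n_resolutions=2, grid_spacing_finest=48, max_iterations_per_level=50, seed=0)


@pytest.fixture(scope="session")
def healthy_subject():
    return generate_subject(PhantomParams(seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)

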
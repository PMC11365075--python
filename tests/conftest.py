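import numpy as np
import pytest

from translung.phantom import PhantomParams, generate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_params():
    """Desk-scale phantom parameters used across tests."""
    return PhantomParams(image_size=64)


@pytest.fixture(scope="session")
def tiny_split(small_params):
    """A small train/test phantom split for fast pipeline tests."""
    return generate_dataset(4, 2, small_params, seed=7)
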
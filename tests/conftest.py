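import numpy as np
import pytest

from usfusion.synthetic import SyntheticParams, generate_paired_patches


@pytest.fixture(scope="session")
def small_params():
    return SyntheticParams(seed=7, n_per_class=12)


@pytest.fixture(scope="session")
def small_patches(small_params):
    return generate_paired_patches(small_params)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
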
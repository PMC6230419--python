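import numpy as np
import pytest

from segbrain.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_spec():
    """A 32x32 phantom spec small enough for fast unit tests."""
    return PhantomSpec(height=32, width=32, seed=3)


@pytest.fixture
def small_pair(small_spec):
    return generate_phantom(small_spec)
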
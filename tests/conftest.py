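import numpy as np
import pytest

from latsurr import FBFSpec, Lattice, fbf_generate, binarize_median


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fbf32():
    """A 32x32 continuous fractional Brownian field, beta=3."""
    return fbf_generate(FBFSpec(beta=3.0, seed=42))


@pytest.fixture
def fbf32_pair():
    a = fbf_generate(FBFSpec(beta=1.5, seed=101))
    b = fbf_generate(FBFSpec(beta=1.5, seed=202))
    return a, b


@pytest.fixture
def binary32():
    return binarize_median(fbf_generate(FBFSpec(beta=3.0, seed=7)))


@pytest.fixture
def small_lattice():
    return Lattice(np.arange(16, dtype=float).reshape(4, 4))
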
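import numpy as np
import pytest

from phylodup.simulate import build_fixture


@pytest.fixture(scope="session")
def mini():
    """Canned 16-species bundle with a planted Maleae-crown WGD."""
    return build_fixture("rosaceae_mini")


@pytest.fixture(scope="session")
def bench():
    """Noise-free 200-family bundle, first 30 families NNI-perturbed."""
    return build_fixture("filter_bench")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
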
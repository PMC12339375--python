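import numpy as np
import pytest

from covani.sketch import SketchParams


@pytest.fixture(scope="session")
def default_params():
    return SketchParams()


@pytest.fixture(scope="session")
def dense_params():
    """c=1 keeps every k-mer: sketching reduces to exact k-mer counting."""
    return SketchParams(c=1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
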
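import numpy as np
import pytest

from mcprofiler.classification import default_prototypes
from mcprofiler.discovery import Epilocus
from mcprofiler.profiles import MCProfile


@pytest.fixture(scope="session")
def prototypes():
    return default_prototypes()


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_profile(rng, concentration=1.0):
    """A random point on the 5-class simplex (Dirichlet)."""
    return MCProfile(tuple(rng.dirichlet([concentration] * 5)))


@pytest.fixture
def small_epiloci():
    """Three well-separated epiloci on one synthetic chromosome."""
    return [
        Epilocus("chrS", (100, 110, 120, 130)),
        Epilocus("chrS", (300, 312, 324, 336)),
        Epilocus("chrS", (500, 505, 540, 560)),
    ]
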
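import numpy as np
import pytest

from beeal.topology import LayoutSpec, build_topology


@pytest.fixture(scope="session")
def default_connectome():
    return build_topology(LayoutSpec(seed=3))


@pytest.fixture(scope="session")
def micro_connectome():
    """4-glomerulus network (32 neurons) for fast simulator tests."""
    return build_topology(LayoutSpec(n_glomeruli=4, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
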
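import numpy as np
import pytest
from hypothesis import settings

import circuitscreen as cs
from circuitscreen.engine import ParameterSet

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def toy_circuits():
    return cs.make_toy_circuits()


@pytest.fixture
def paper_net():
    return cs.twist1_emt_cin_network()


@pytest.fixture
def small_config():
    """Reduced ensemble sizes for fast unit tests."""
    return cs.SamplingConfig(n_param_sets=20, n_init=20, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(123)


def toggle_params(net, b0=50.0, g=50.0, k=0.5, n=4, lam=0.01):
    """Symmetric mutual-inhibition parameterization (bistable at b0=50)."""
    return ParameterSet(
        node_names=net.nodes,
        g=np.array([g, g]),
        k=np.array([k, k]),
        edge_src=np.array([0, 1]),
        edge_tgt=np.array([1, 0]),
        b0=np.array([b0, b0]),
        n=np.array([n, n], dtype=np.int64),
        lam=np.array([lam, lam]),
    )
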
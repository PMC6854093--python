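import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=40,
    # tmp_path reuse across examples is safe: files get unique names
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def triangle_pendant():
    """Triangle {a,b,c} with pendant d attached to a."""
    return nx.Graph([("a", "b"), ("a", "c"), ("b", "c"), ("a", "d")])


def random_graph(n_nodes: int, p: float, seed: int) -> nx.Graph:
    g = nx.gnp_random_graph(n_nodes, p, seed=seed)
    return g
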
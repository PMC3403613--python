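import itertools

import networkx as nx
import numpy as np
import pytest


def make_barbell(m: int) -> nx.Graph:
    """Two K_m joined by a single bridge edge, string-labelled."""
    net = nx.relabel_nodes(nx.barbell_graph(m, 0), lambda x: f"v{x:02d}")
    return net


def bridge_edge(m: int) -> tuple:
    return (f"v{m - 1:02d}", f"v{m:02d}")


def random_graph(rng: np.random.Generator, n_max: int = 12) -> nx.Graph:
    """Small random graph with string labels, arbitrary density, maybe isolates."""
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.1, 0.9))
    net = nx.Graph()
    net.add_nodes_from(f"n{i}" for i in range(n))
    for u, v in itertools.combinations(range(n), 2):
        if rng.random() < p:
            net.add_edge(f"n{u}", f"n{v}")
    return net


@pytest.fixture
def barbell4():
    return make_barbell(4)


@pytest.fixture
def triangle_pendant():
    """Triangle a-b-c with a pendant vertex d hanging off a."""
    net = nx.Graph()
    net.add_edges_from([("a", "b"), ("a", "c"), ("b", "c"), ("a", "d")])
    return net
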
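import numpy as np
import pytest

import mndiff as m


@pytest.fixture
def path_graph():
    """A-B-C-D path: degrees (1, 2, 2, 1)."""
    return m.from_edges([("A", "B"), ("B", "C"), ("C", "D")])


@pytest.fixture
def triangle():
    return m.from_edges([("A", "B"), ("B", "C"), ("A", "C")])


def random_instance(rng, n_min=10, n_max=60, L=2, p=None):
    """Random Erdős–Rényi network with i.i.d. uniform scores, aligned."""
    import networkx as nx

    n = int(rng.integers(n_min, n_max + 1))
    p = p if p is not None else rng.uniform(0.05, 0.3)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    net = m.from_networkx(g)
    X = rng.uniform(0, 1, size=(n, L))
    sm = m.ScoreMatrix(net.genes, [f"L{i+1}" for i in range(L)], X)
    return net, sm
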
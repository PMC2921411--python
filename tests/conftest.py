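import numpy as np
import pytest

from pyramabs.network_io import WeightedNetwork
from pyramabs.proximity import ProximityNetwork


def pnet_from_dict(prox: dict[tuple[str, str], float], nodes=None) -> ProximityNetwork:
    """Build a ProximityNetwork directly from ordered-pair values."""
    if nodes is None:
        seen: dict[str, None] = {}
        for u, v in prox:
            seen.setdefault(u)
            seen.setdefault(v)
        nodes = tuple(seen)
    else:
        nodes = tuple(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    M = np.zeros((len(nodes), len(nodes)))
    for (u, v), p in prox.items():
        M[idx[u], idx[v]] = p
    return ProximityNetwork(nodes, M, M > 0)


@pytest.fixture
def two_clique_bridge():
    """Two tight 3-cliques joined by one weak bridge; symmetric proximities."""
    prox = {}
    for a, b in [("a1", "a2"), ("a1", "a3"), ("a2", "a3"),
                 ("b1", "b2"), ("b1", "b3"), ("b2", "b3")]:
        prox[(a, b)] = prox[(b, a)] = 10.0
    prox[("a3", "b1")] = prox[("b1", "a3")] = 1.0
    return pnet_from_dict(prox, nodes=["a1", "a2", "a3", "b1", "b2", "b3"])


@pytest.fixture
def uniform_star():
    """Hub with four leaves, uniform proximity, no leaf-leaf association."""
    prox = {}
    for leaf in ["l1", "l2", "l3", "l4"]:
        prox[("h", leaf)] = prox[(leaf, "h")] = 1.0
    return pnet_from_dict(prox, nodes=["h", "l1", "l2", "l3", "l4"])


def random_network(rng: np.random.Generator, n: int, p: float = 0.5,
                   weighted: bool = True, directed: bool = False) -> WeightedNetwork:
    nodes = [f"v{i}" for i in range(n)]
    edges = []
    for i in range(n):
        js = range(n) if directed else range(i + 1, n)
        for j in js:
            if i != j and rng.random() < p:
                w = float(rng.integers(1, 10)) if weighted else 1.0
                edges.append((nodes[i], nodes[j], w))
    return WeightedNetwork.from_edges(edges, directed=directed, nodes=nodes)
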
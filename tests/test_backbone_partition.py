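from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from pyramabs import maximum_spanning_forest, partition, symmetrize

from conftest import pnet_from_dict


# -- symmetrize -----------------------------------------------------------


def test_symmetrize_sums_both_directions():
    pn = pnet_from_dict({("a", "b"): 2.0, ("b", "a"): 3.0})
    assert symmetrize(pn) == {("a", "b"): 5.0}


def test_symmetrize_missing_direction_counts_zero():
    pn = pnet_from_dict({("a", "b"): 2.0})
    assert symmetrize(pn) == {("a", "b"): 2.0}


def test_symmetrize_doubles_symmetric_input():
    pn = pnet_from_dict({("a", "b"): 2.0, ("b", "a"): 2.0})
    assert symmetrize(pn) == {("a", "b"): 4.0}


# -- maximum spanning forest ----------------------------------------------


def brute_force_max_spanning_weight(weights, nodes):
    """Oracle: enumerate all edge subsets forming a spanning forest with the
    maximal per-component edge count, track the best total weight."""
    G = nx.Graph()
    G.add_nodes_from(nodes)
    for (u, v), w in weights.items():
        G.add_edge(u, v, weight=w)
    needed = len(nodes) - nx.number_connected_components(G)
    best = 0.0
    edges = list(weights.items())
    for combo in combinations(edges, needed):
        H = nx.Graph()
        H.add_nodes_from(nodes)
        H.add_edges_from((u, v) for (u, v), _ in combo)
        if nx.number_connected_components(H) == nx.number_connected_components(G):
            best = max(best, sum(w for _, w in combo))
    return best


def test_triangle_takes_two_heaviest_edges():
    weights = {("A", "B"): 3.0, ("B", "C"): 2.0, ("A", "C"): 1.0}
    bb = maximum_spanning_forest(weights, {"A", "B", "C"})
    assert bb.n_trees == 1
    chosen = {(u, v) for _, es in bb.trees for u, v, _ in es}
    assert chosen == {("A", "B"), ("B", "C")}
    assert bb.total_weight == pytest.approx(5.0)


def test_tree_input_is_returned_unchanged():
    weights = {("a", "b"): 1.0, ("b", "c"): 2.0, ("c", "d"): 0.5}
    bb = maximum_spanning_forest(weights, {"a", "b", "c", "d"})
    assert bb.total_weight == pytest.approx(3.5)
    assert sum(len(es) for _, es in bb.trees) == 3


def test_disjoint_edges_yield_two_trees_and_isolates_get_singletons():
    weights = {("a", "b"): 1.0, ("c", "d"): 1.0}
    bb = maximum_spanning_forest(weights, {"a", "b", "c", "d", "e"})
    assert bb.n_trees == 3
    assert bb.covered_nodes == {"a", "b", "c", "d", "e"}
    assert any(ns == {"e"} and not es for ns, es in bb.trees)


def test_forest_weight_matches_brute_force_and_networkx():
    rng = np.random.default_rng(17)
    for _ in range(200):
        n = int(rng.integers(3, 8))
        nodes = {f"v{i}" for i in range(n)}
        weights = {
            (f"v{i}", f"v{j}"): float(rng.integers(1, 20))
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < 0.5
        }
        bb = maximum_spanning_forest(weights, nodes)
        assert bb.total_weight == pytest.approx(
            brute_force_max_spanning_weight(weights, nodes)
        )
        G = nx.Graph()
        G.add_nodes_from(nodes)
        for (u, v), w in weights.items():
            G.add_edge(u, v, weight=w)
        T = nx.maximum_spanning_tree(G)
        assert bb.total_weight == pytest.approx(
            sum(w for _, _, w in T.edges(data="weight"))
        )


def test_negative_weights_rejected():
    with pytest.raises(ValueError):
        maximum_spanning_forest({("a", "b"): -1.0}, {"a", "b"})


# -- partition -------------------------------------------------------------


def _backbone_of(pnet):
    return maximum_spanning_forest(symmetrize(pnet), frozenset(pnet.nodes))


def module_criterion_holds(module_set, pnet):
    """Pairwise criterion on the scored network, with the zero-inter
    exception for disconnected modules."""
    P = pnet.masked_matrix()
    idx = {n: i for i, n in enumerate(pnet.nodes)}
    mods = [sorted(idx[n] for n in m) for m in module_set.modules]
    for a in range(len(mods)):
        for b in range(a + 1, len(mods)):
            inter = P[np.ix_(mods[a], mods[b])].sum() + P[np.ix_(mods[b], mods[a])].sum()
            if inter == 0:
                continue
            ia = P[np.ix_(mods[a], mods[a])].sum()
            ib = P[np.ix_(mods[b], mods[b])].sum()
            if not (ia > inter and ib > inter):
                return False
    return True


def test_two_cliques_split_at_the_bridge(two_clique_bridge):
    ms = partition(_backbone_of(two_clique_bridge), two_clique_bridge)
    assert sorted(sorted(m) for m in ms.modules) == [
        ["a1", "a2", "a3"],
        ["b1", "b2", "b3"],
    ]
    assert module_criterion_holds(ms, two_clique_bridge)


def test_uniform_star_refuses_to_split(uniform_star):
    ms = partition(_backbone_of(uniform_star), uniform_star)
    assert ms.n_modules == 1
    # brute check: every cut isolates a leaf with zero intra, never admissible
    P = uniform_star.masked_matrix()
    idx = {n: i for i, n in enumerate(uniform_star.nodes)}
    for leaf in ["l1", "l2", "l3", "l4"]:
        li = idx[leaf]
        rest = [i for i in range(5) if i != li]
        assert P[li, li] == 0.0  # S_intra of the singleton
        assert P[np.ix_([li], rest)].sum() + P[np.ix_(rest, [li])].sum() > 0


def test_single_node_is_a_singleton_module():
    pn = pnet_from_dict({}, nodes=["only"])
    ms = partition(_backbone_of(pn), pn)
    assert ms.modules == [frozenset(["only"])]


def test_partition_conserves_nodes_and_satisfies_criterion_on_random_fixtures():
    rng = np.random.default_rng(23)
    for _ in range(25):
        n = int(rng.integers(2, 12))
        nodes = [f"v{i}" for i in range(n)]
        prox = {}
        for i in range(n):
            for j in range(n):
                if i != j and rng.random() < 0.4:
                    prox[(nodes[i], nodes[j])] = float(rng.integers(1, 10))
        pn = pnet_from_dict(prox, nodes=nodes)
        ms = partition(_backbone_of(pn), pn)
        assert sorted(x for m in ms.modules for x in m) == sorted(nodes)
        assert module_criterion_holds(ms, pn)


def exhaustive_feasible_partitions(pnet):
    """Oracle: all partitions reachable by removing any subset of backbone
    links that satisfy the pairwise criterion."""
    bb = _backbone_of(pnet)
    all_edges = [e for _, es in bb.trees for e in es]
    feasible = []
    for r in range(len(all_edges) + 1):
        for removed in combinations(range(len(all_edges)), r):
            G = nx.Graph()
            G.add_nodes_from(pnet.nodes)
            for i, (u, v, _) in enumerate(all_edges):
                if i not in removed:
                    G.add_edge(u, v)
            mods = [frozenset(c) for c in nx.connected_components(G)]

            class _MS:
                modules = mods

            if module_criterion_holds(_MS, pnet):
                feasible.append(mods)
    return feasible


def test_greedy_result_is_among_exhaustively_feasible_partitions():
    rng = np.random.default_rng(31)
    for _ in range(10):
        n = int(rng.integers(3, 9))
        nodes = [f"v{i}" for i in range(n)]
        prox = {}
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.5:
                    w = float(rng.integers(1, 10))
                    prox[(nodes[i], nodes[j])] = w
                    prox[(nodes[j], nodes[i])] = w
        pn = pnet_from_dict(prox, nodes=nodes)
        ms = partition(_backbone_of(pn), pn)
        feasible = exhaustive_feasible_partitions(pn)
        assert sorted(map(sorted, ms.modules)) in [
            sorted(map(sorted, f)) for f in feasible
        ]


def test_partition_is_deterministic(two_clique_bridge):
    a = partition(_backbone_of(two_clique_bridge), two_clique_bridge)
    b = partition(_backbone_of(two_clique_bridge), two_clique_bridge)
    assert a.modules == b.modules
    assert a.intra == b.intra and a.inter == b.inter


def test_isolated_nodes_become_flagged_singletons():
    pn = pnet_from_dict(
        {("a", "b"): 5.0, ("b", "a"): 5.0}, nodes=["a", "b", "lone"]
    )
    ms = partition(_backbone_of(pn), pn)
    assert frozenset(["lone"]) in ms.modules
    lone_id = [mid for mid, m in ms.as_dict().items() if m == frozenset(["lone"])][0]
    assert lone_id in ms.singleton_exceptions
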
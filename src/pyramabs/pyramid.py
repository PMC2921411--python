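"""Building the abstraction pyramid.

One construction round on the current network: compute the node proximity,
z-filter the weak pairs, extract the spanning-forest backbone of the
symmetrised survivors, partition by admissible cuts, then collapse every
module to a supernode. Supernode link weights are size-normalised averages
of the UN-thresholded proximities between member nodes,

    prox_super(M_a, M_b) = 1 / (|M_a| |M_b|) * sum_{m in M_a, n in M_b} prox(m, n)

and that abstract network becomes the next round's input adjacency. Rounds
repeat until a single supernode remains, the partition stops coarsening
(stall), or a safety level cap is hit. Internally levels are built bottom-up;
reported level numbers put 1 at the top.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .backbone_partition import ModuleSet, maximum_spanning_forest, partition, symmetrize
from .network_io import WeightedNetwork
from .proximity import ProximityNetwork, compute_proximity, zscore_filter

logger = logging.getLogger("pyramabs")

__all__ = ["PyramidLevel", "Pyramid", "build_supernode_network", "build_pyramid"]


@dataclass
class PyramidLevel:
    """One level: its input network, the module cover, and the abstraction."""

    input_network: WeightedNetwork
    module_set: ModuleSet
    abstract_network: WeightedNetwork
    parent_of: dict[str, str]

    @property
    def n_isolated_supernodes(self) -> int:
        """Modules flagged as isolated in the thresholded graph of this level."""
        return len(self.module_set.singleton_exceptions)


@dataclass
class Pyramid:
    """Ordered levels from bottom (original network) to top."""

    levels: list[PyramidLevel]
    params: dict
    stalled: bool = False

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def flattened_memberships(self) -> list[dict[str, str]]:
        """Original-node → module-id maps, one per level, bottom to top.

        Entry ℓ assigns every node of the original network to its module at
        internal level ℓ by composing the per-level parent maps.
        """
        out: list[dict[str, str]] = []
        current = {n: n for n in self.levels[0].input_network.nodes}
        for level in self.levels:
            current = {orig: level.parent_of[cur] for orig, cur in current.items()}
            out.append(dict(current))
        return out

    def module_counts(self) -> list[int]:
        """Module count per level, bottom to top."""
        return [lvl.module_set.n_modules for lvl in self.levels]

    @property
    def n_isolated_supernodes(self) -> int:
        return sum(lvl.n_isolated_supernodes for lvl in self.levels)


def build_supernode_network(
    module_set: ModuleSet, pnet: ProximityNetwork, directed: bool = False
) -> WeightedNetwork:
    """Collapse modules to supernodes with size-normalised proximity averages.

    Uses the proximity values as stored in ``pnet`` — the pyramid loop passes
    the un-thresholded proximity network here, so weak-but-real inter-module
    association survives the abstraction. Zero-weight pairs are not stored.
    """
    if module_set.covered() != frozenset(pnet.nodes):
        raise ValueError("module set does not partition the proximity network's nodes")
    P = pnet.masked_matrix()
    k = module_set.n_modules
    n = len(pnet.nodes)
    index = {node: i for i, node in enumerate(pnet.nodes)}
    Z = np.zeros((n, k))
    sizes = np.zeros(k)
    for a, members in enumerate(module_set.modules):
        sizes[a] = len(members)
        for node in members:
            Z[index[node], a] = 1.0
    W = (Z.T @ P @ Z) / np.outer(sizes, sizes)
    np.fill_diagonal(W, 0.0)
    # the proximity is asymmetric whenever node strengths differ (the i -> j
    # denominator is W_i - A_ij), so module averages of an undirected level
    # generally form a directed abstract network
    if not directed and np.allclose(W, W.T):
        W = (W + W.T) / 2.0
        return WeightedNetwork.from_adjacency(W, module_set.module_ids, directed=False)
    return WeightedNetwork.from_adjacency(W, module_set.module_ids, directed=True)


def build_pyramid(
    net: WeightedNetwork, z_threshold: float = 0.0, max_levels: int = 50
) -> Pyramid:
    """Iterate the abstraction loop until one supernode remains or it stalls.

    Termination: success when the abstract network has a single node; stall
    when a round produces as many modules as it has nodes (no coarsening) or
    when ``max_levels`` rounds have run. A stalled pyramid is returned with
    ``stalled`` set rather than raising.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot build a pyramid from an empty network")
    if max_levels < 1:
        raise ValueError("max_levels must be >= 1")
    params = {
        "z_threshold": float(z_threshold),
        "directed": net.directed,
        "max_levels": int(max_levels),
    }
    levels: list[PyramidLevel] = []
    current = net
    stalled = False
    for round_no in range(max_levels):
        level, coarsened = _build_level(current, z_threshold, round_no)
        levels.append(level)
        logger.info(
            "level %d: %d nodes, %d links, %d modules",
            round_no,
            current.n_nodes,
            current.n_links,
            level.module_set.n_modules,
        )
        if level.abstract_network.n_nodes == 1:
            break
        if not coarsened:
            stalled = True
            break
        current = level.abstract_network
    else:
        stalled = True
    return Pyramid(levels=levels, params=params, stalled=stalled)


def _build_level(
    net: WeightedNetwork, z_threshold: float, round_no: int
) -> tuple[PyramidLevel, bool]:
    if net.n_nodes == 1:
        module_set = ModuleSet(
            [frozenset(net.nodes)], module_ids=[f"s{round_no}_0"]
        )
        abstract = WeightedNetwork([f"s{round_no}_0"], directed=net.directed)
        parent_of = {net.nodes[0]: f"s{round_no}_0"}
        return PyramidLevel(net, module_set, abstract, parent_of), True
    pnet = compute_proximity(net)
    if pnet.n_pairs == 0:
        # no links at all: every node is its own module, nothing coarsens
        ids = [f"s{round_no}_{i}" for i in range(net.n_nodes)]
        module_set = ModuleSet(
            [frozenset([n]) for n in net.nodes],
            module_ids=ids,
            singleton_exceptions=frozenset(ids),
        )
        abstract = WeightedNetwork(ids, directed=net.directed)
        parent_of = dict(zip(net.nodes, ids))
        return PyramidLevel(net, module_set, abstract, parent_of), False
    filtered = zscore_filter(pnet, z_threshold)
    weights = symmetrize(filtered)
    backbone = maximum_spanning_forest(weights, frozenset(net.nodes))
    module_set = partition(backbone, filtered)
    module_set = module_set.renamed(
        [f"s{round_no}_{i}" for i in range(module_set.n_modules)]
    )
    abstract = build_supernode_network(module_set, pnet, directed=net.directed)
    parent_of = module_set.membership()
    coarsened = module_set.n_modules < net.n_nodes
    return PyramidLevel(net, module_set, abstract, parent_of), coarsened
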
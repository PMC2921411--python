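"""Hierarchically nested random network generator.

The benchmark substrate: n nodes carry a planted nested module structure
(by default 4 top modules of 160 nodes, each split into 4 of 40, each into
4 of 10), and each unordered node pair receives an edge independently with a
probability that decays geometrically with the pair's hierarchical distance,

    p_d = c * rho**d,    d = 0 .. D,

where d is the number of hierarchy levels one must climb before the pair
shares a module (d = 0: same bottom module; d = D: no shared module) and
rho in (0, 1] is the cohesion knob — smaller rho concentrates edges inside
bottom modules. The constant c is calibrated in closed form so that the
expected edge count matches a target density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network_io import WeightedNetwork

__all__ = [
    "GeneratorSpec",
    "NestedPartition",
    "calibrate_probabilities",
    "generate",
    "thin_to_density",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the nested random network ensemble.

    branching lists modules-per-parent from the top level down; leaf_size is
    the bottom module size. Defaults reproduce the 640-node three-level
    benchmark at density 0.0225 with rho = 0.25.
    """

    branching: tuple[int, ...] = (4, 4, 4)
    leaf_size: int = 10
    target_density: float = 0.0225
    rho: float = 0.25
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "branching", tuple(int(b) for b in self.branching))
        if not self.branching or any(b < 2 for b in self.branching):
            raise ValueError("branching factors must all be >= 2")
        if self.leaf_size < 1:
            raise ValueError("leaf_size must be >= 1")
        if not 0 < self.target_density <= 1:
            raise ValueError("target_density must be in (0, 1]")
        if not 0 < self.rho <= 1:
            raise ValueError("rho must be in (0, 1]")

    @property
    def n_nodes(self) -> int:
        return self.leaf_size * int(np.prod(self.branching))

    @property
    def depth(self) -> int:
        """D: hierarchical distance of a pair sharing no module."""
        return len(self.branching)

    def module_sizes(self) -> list[int]:
        """Size of the containing module at distance d, for d = 0 .. D."""
        sizes = [self.leaf_size]
        for b in reversed(self.branching):
            sizes.append(sizes[-1] * b)
        return sizes

    def partner_counts(self) -> list[int]:
        """Number of partners of one node at each hierarchical distance d."""
        sizes = self.module_sizes()
        counts = [self.leaf_size - 1]
        counts.extend(sizes[d] - sizes[d - 1] for d in range(1, len(sizes)))
        return counts


@dataclass
class NestedPartition:
    """Planted nested module structure: partitions from top to bottom."""

    levels: list[dict[str, str]]
    branching: tuple[int, ...]
    leaf_size: int
    nodes: tuple[str, ...] = field(default=())

    def level_sizes(self) -> list[int]:
        """Module count per level, top to bottom."""
        return [len(set(level.values())) for level in self.levels]

    def is_nested(self) -> bool:
        """Each level refines the one above it."""
        for upper, lower in zip(self.levels, self.levels[1:]):
            parent_of: dict[str, str] = {}
            for node, sub in lower.items():
                if parent_of.setdefault(sub, upper[node]) != upper[node]:
                    return False
        return True


def calibrate_probabilities(spec: GeneratorSpec) -> list[float]:
    """Per-distance edge probabilities p_d = c * rho**d matching the density.

    c solves  sum_d count_d * c * rho**d = target_density * (n - 1), i.e. the
    expected degree under the tier law equals the expected degree of an
    Erdos-Renyi graph at the target density.
    """
    counts = spec.partner_counts()
    weights = sum(c * spec.rho**d for d, c in enumerate(counts))
    c = spec.target_density * (spec.n_nodes - 1) / weights
    if c > 1.0 + 1e-12:
        raise ValueError(
            f"calibration requires p_0 = {c:.4f} > 1; "
            "increase rho or lower target_density"
        )
    return [min(c * spec.rho**d, 1.0) for d in range(len(counts))]


def planted_partition(spec: GeneratorSpec) -> NestedPartition:
    """The deterministic planted structure (independent of the seed)."""
    n = spec.n_nodes
    width = len(str(n - 1))
    nodes = tuple(f"n{i:0{width}d}" for i in range(n))
    sizes = spec.module_sizes()[:-1][::-1]  # top-level module size first
    levels = []
    for t, g in enumerate(sizes, start=1):
        levels.append({nodes[i]: f"t{t}_{i // g}" for i in range(n)})
    return NestedPartition(
        levels=levels, branching=spec.branching, leaf_size=spec.leaf_size, nodes=nodes
    )


def generate(spec: GeneratorSpec) -> tuple[WeightedNetwork, NestedPartition]:
    """Sample one undirected unit-weight network with its planted truth."""
    probs = np.asarray(calibrate_probabilities(spec))
    truth = planted_partition(spec)
    n = spec.n_nodes
    idx = np.arange(n)
    # hierarchical distance matrix: D minus the number of shared levels
    D = spec.depth
    dist = np.full((n, n), D, dtype=np.int64)
    for g in spec.module_sizes()[:-1]:
        grp = idx // g
        dist -= grp[:, None] == grp[None, :]
    iu, ju = np.triu_indices(n, k=1)
    rng = np.random.default_rng(spec.seed)
    draw = rng.random(iu.size) < probs[dist[iu, ju]]
    A = np.zeros((n, n))
    A[iu[draw], ju[draw]] = 1.0
    A += A.T
    net = WeightedNetwork.from_adjacency(A, truth.nodes, directed=False)
    return net, truth


def thin_to_density(
    net: WeightedNetwork, target_density: float, seed: int
) -> WeightedNetwork:
    """Remove uniformly random links until exactly the target link count.

    The retained count is floor(target_density * n(n-1)/2), so density sweeps
    are noiseless in link count.
    """
    if net.directed:
        raise ValueError("thinning is defined for undirected networks")
    n = net.n_nodes
    # epsilon guards the floor against float error when the target equals the
    # current density exactly
    target_links = int(np.floor(target_density * n * (n - 1) / 2 + 1e-9))
    links = sorted(
        (u, v, w) for u, v, w in net.links() if u < v
    )
    if target_links > len(links):
        raise ValueError(
            f"target density {target_density} exceeds current density "
            f"({len(links)} links available, {target_links} requested)"
        )
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(links), size=target_links, replace=False)
    kept = [links[i] for i in sorted(keep.tolist())]
    return WeightedNetwork.from_edges(kept, directed=False, nodes=net.nodes)
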
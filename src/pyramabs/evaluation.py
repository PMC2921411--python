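"""Scoring recovered hierarchies against planted truth.

Agreement between two flat partitions is normalised mutual information,
NMI = 2 I(P;Q) / (H(P) + H(Q)), which is 1 for identical partitions and 0
for independent ones. A recovered pyramid is compared level-by-level to a
planted nested partition: each truth level is matched to the recovered level
at the same depth from the top, after dropping trivial single-module levels
(the pyramid's root).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import normalized_mutual_info_score

from .generator import NestedPartition
from .network_io import WeightedNetwork
from .pyramid import Pyramid

__all__ = [
    "FlatPartition",
    "HierarchyReport",
    "normalized_mutual_information",
    "evaluate_hierarchy",
    "density",
]


@dataclass(frozen=True)
class FlatPartition:
    """A single-level clustering: total assignment of a node universe."""

    assignment: dict[str, str]
    universe: frozenset[str]

    def __post_init__(self):
        if set(self.assignment) != set(self.universe):
            raise ValueError("assignment is not total on the universe")

    @classmethod
    def from_assignment(cls, assignment: dict[str, str]) -> "FlatPartition":
        return cls(dict(assignment), frozenset(assignment))

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def normalized_mutual_information(p: FlatPartition, q: FlatPartition) -> float:
    """NMI = 2 I(P;Q) / (H(P) + H(Q)) with natural-log entropies.

    Conventions at zero entropy: two all-in-one partitions agree perfectly
    (1.0); if exactly one side is all-in-one the score is 0.0, so the trivial
    partition never scores well against a structured one.
    """
    if p.universe != q.universe:
        raise ValueError("partitions cover different node universes")
    nodes = sorted(p.universe)
    lp = np.asarray([p.assignment[n] for n in nodes])
    lq = np.asarray([q.assignment[n] for n in nodes])
    hp, hq = _entropy(lp), _entropy(lq)
    if hp == 0.0 and hq == 0.0:
        return 1.0
    if hp == 0.0 or hq == 0.0:
        return 0.0
    return float(normalized_mutual_info_score(lp, lq, average_method="arithmetic"))


@dataclass
class HierarchyReport:
    """Per-level NMI of a recovered pyramid against planted truth.

    ``levels`` holds one entry per truth level (top first): the truth depth,
    the recovered level used, its module count, the NMI, and whether the
    match was flagged (no recovered level at that exact depth).
    """

    levels: list[dict]
    mean_nmi: float
    pred_module_counts: list[int]

    @property
    def flagged(self) -> bool:
        return any(entry["flagged"] for entry in self.levels)


def evaluate_hierarchy(pred: Pyramid, truth: NestedPartition) -> HierarchyReport:
    """Score each planted level against the recovered level at the same depth.

    Recovered levels are the pyramid's flattened memberships ordered top to
    bottom, excluding single-module levels. If fewer recovered levels exist
    than truth levels, the deepest available one is reused and flagged.
    """
    truth_universe = frozenset(truth.levels[0]) if truth.levels else frozenset()
    pred_universe = frozenset(pred.levels[0].input_network.nodes)
    if truth_universe != pred_universe:
        raise ValueError("pyramid and planted truth cover different node sets")
    flat = pred.flattened_memberships()[::-1]  # top -> bottom
    informative = [
        FlatPartition.from_assignment(m) for m in flat if len(set(m.values())) > 1
    ]
    entries = []
    scores = []
    for depth, truth_level in enumerate(truth.levels):
        tp = FlatPartition.from_assignment(truth_level)
        if depth < len(informative):
            pp = informative[depth]
            flagged = False
        elif informative:
            pp = informative[-1]
            flagged = True
        else:
            pp = FlatPartition(
                {n: "all" for n in truth_universe}, truth_universe
            )
            flagged = True
        nmi = normalized_mutual_information(tp, pp)
        scores.append(nmi)
        entries.append(
            {
                "truth_depth": depth,
                "truth_modules": tp.n_clusters,
                "pred_modules": pp.n_clusters,
                "nmi": nmi,
                "flagged": flagged,
            }
        )
    return HierarchyReport(
        levels=entries,
        mean_nmi=float(np.mean(scores)) if scores else 0.0,
        pred_module_counts=[p.n_clusters for p in informative],
    )


def density(net: WeightedNetwork) -> float:
    """Fraction of realised links among possible pairs (weights ignored)."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("density requires at least 2 nodes")
    if net.directed:
        return net.n_links / (n * (n - 1))
    return 2.0 * net.n_links / (n * (n - 1))
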
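"""Node proximity and z-score link filtering.

The proximity from node i to node j combines the direct link weight with
probability-weighted contributions of every two-step path through a common
neighbour k:

    prox(i, j) = A_ij + sum_k  A_ik / (W_i - A_ij) * A_kj / W_k * min(A_ik, A_kj)

where W_i is the total outgoing weight of i and the sum runs over all k with
A_ik > 0 and A_kj > 0. The first factor is the probability that i affects k
given that the direct link to j is set aside, the second the probability that
k affects j, and min(A_ik, A_kj) scales the contribution by the weaker of the
two sub-path weights. Pairs with neither a direct link nor a common neighbour
have proximity zero and are never stored.

Filtering standardises all stored proximities of a level (population z-score)
and keeps the pairs at or above a threshold, the search-space reduction step
of the pyramid construction.
"""

from __future__ import annotations

from collections.abc import Iterator

import numpy as np

from .network_io import WeightedNetwork

__all__ = ["ProximityNetwork", "compute_proximity", "zscore_filter"]


class ProximityNetwork:
    """Directed proximity values between node pairs of one pyramid level.

    Backed by a dense matrix plus a boolean mask of stored pairs; pairs with
    proximity zero are never stored, so they never enter the z-score
    population. ``threshold_applied`` records the z-score cut, if any.
    """

    def __init__(
        self,
        nodes: tuple[str, ...],
        matrix: np.ndarray,
        mask: np.ndarray,
        threshold_applied: float | None = None,
    ):
        self.nodes = nodes
        self._index = {n: i for i, n in enumerate(nodes)}
        self.matrix = matrix
        self.mask = mask
        self.threshold_applied = threshold_applied

    @property
    def n_pairs(self) -> int:
        """Number of stored ordered pairs."""
        return int(self.mask.sum())

    def get(self, u: str, v: str) -> float:
        i, j = self._index[u], self._index[v]
        return float(self.matrix[i, j]) if self.mask[i, j] else 0.0

    def items(self) -> Iterator[tuple[str, str, float]]:
        src, dst = np.nonzero(self.mask)
        for i, j in zip(src.tolist(), dst.tolist()):
            yield self.nodes[i], self.nodes[j], float(self.matrix[i, j])

    def values(self) -> np.ndarray:
        """Stored proximity values (the z-score population)."""
        return self.matrix[self.mask]

    def masked_matrix(self) -> np.ndarray:
        """Dense matrix with unstored pairs zeroed."""
        return np.where(self.mask, self.matrix, 0.0)

    def zscores(self) -> dict[tuple[str, str], float]:
        """Population z-score of every stored pair."""
        vals = self.matrix[self.mask]
        mu = vals.mean()
        sigma = vals.std()  # population sd (ddof=0)
        out: dict[tuple[str, str], float] = {}
        for u, v, p in self.items():
            out[(u, v)] = 0.0 if sigma == 0 else (p - mu) / sigma
        return out


def compute_proximity(net: WeightedNetwork) -> ProximityNetwork:
    """Compute the proximity between every ordered node pair of ``net``.

    Vectorised over common neighbours: for each k, the contributions
    A_ik * A_kj / W_k * min(A_ik, A_kj) are accumulated into S_ij by an outer
    product over k's in- and out-neighbours, and the pair-dependent
    denominator W_i - A_ij is applied once at the end. Nodes with zero
    outgoing weight contribute no outgoing proximity.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot compute proximity of an empty network")
    A = np.asarray(net.adjacency)
    n = A.shape[0]
    W = A.sum(axis=1)
    S = np.zeros((n, n))
    for k in range(n):
        if W[k] == 0:
            continue
        src = np.nonzero(A[:, k])[0]  # i with A_ik > 0
        dst = np.nonzero(A[k, :])[0]  # j with A_kj > 0
        if src.size == 0 or dst.size == 0:
            continue
        x = A[src, k]
        y = A[k, dst]
        S[np.ix_(src, dst)] += (
            x[:, None] * (y / W[k])[None, :] * np.minimum(x[:, None], y[None, :])
        )
    np.fill_diagonal(S, 0.0)
    # denominator W_i - A_ij: whenever S_ij > 0 there is a k with A_ik > 0,
    # hence W_i >= A_ij + A_ik > A_ij and the denominator is positive
    denom = W[:, None] - A
    indirect = np.divide(S, denom, out=np.zeros_like(S), where=S > 0)
    P = A + indirect
    np.fill_diagonal(P, 0.0)
    return ProximityNetwork(net.nodes, P, P > 0)


def zscore_filter(pnet: ProximityNetwork, threshold: float = 0.0) -> ProximityNetwork:
    """Keep the links whose population z-score is at or above ``threshold``.

    The population is all stored proximities of the level (both directions
    of a directed network pooled). On an unweighted bottom level this is
    strongly bimodal — direct links near weight 1 versus faint
    common-neighbour-only pairs — so moderate thresholds reduce the graph to
    its direct links; on the weighted abstract levels higher up the
    distribution is continuous and a rising threshold strips progressively
    more links, eventually isolating weakly connected supernodes. A zero
    standard deviation keeps every pair: on a uniform proximity network
    there are no weak outliers to discard.
    """
    if pnet.n_pairs == 0:
        raise ValueError("cannot z-score an empty proximity network")
    vals = pnet.matrix[pnet.mask]
    mu = vals.mean()
    sigma = vals.std()  # population sd (ddof=0)
    if sigma == 0:
        keep = pnet.mask.copy()
    else:
        keep = pnet.mask & ((pnet.matrix - mu) / sigma >= threshold)
    return ProximityNetwork(
        pnet.nodes, pnet.matrix, keep, threshold_applied=float(threshold)
    )
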
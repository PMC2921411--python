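"""Spanning-forest backbone extraction and divisive network partitioning.

The backbone is a maximum-weight spanning forest of the (symmetrised,
thresholded) proximity graph. Partitioning removes backbone links top-down:
cutting a tree link splits its node set into two candidate modules (M_a,
M_b), and the cut is admissible only when both modules cohere more strongly
internally than with each other,

    S_intra(M_a) > S_inter(M_a, M_b)   and   S_intra(M_b) > S_inter(M_a, M_b)

with S_intra(M) the sum of proximities over ordered pairs inside M and
S_inter the sum over ordered pairs between the two modules — both evaluated
on the full thresholded proximity network, not on the tree, so no
information is lost to the backbone reduction. Among admissible cuts the one
with the smallest S_inter is taken and the procedure recurses into both
sides; a subtree with no admissible cut becomes a single module. Because the
cut test is local to the pair being created, a global validation pass then
merges any final module pair that violates the criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .proximity import ProximityNetwork

__all__ = ["Backbone", "ModuleSet", "symmetrize", "maximum_spanning_forest", "partition"]


@dataclass
class Backbone:
    """A maximum-weight spanning forest: node-disjoint trees covering all nodes."""

    trees: list[tuple[frozenset[str], list[tuple[str, str, float]]]]
    covered_nodes: frozenset[str] = field(init=False)

    def __post_init__(self):
        self.covered_nodes = frozenset().union(*(t[0] for t in self.trees)) if self.trees else frozenset()

    @property
    def total_weight(self) -> float:
        return sum(w for _, edges in self.trees for _, _, w in edges)

    @property
    def n_trees(self) -> int:
        return len(self.trees)


class ModuleSet:
    """A disjoint cover of a level's nodes into modules, with cohesion scores.

    ``singleton_exceptions`` records modules that survive only because every
    one of their inter-module sums is zero (isolated nodes of the thresholded
    graph); for these the strict intra > inter criterion is vacuous.
    """

    def __init__(
        self,
        modules: list[frozenset[str]],
        module_ids: list[str] | None = None,
        intra: dict[str, float] | None = None,
        inter: dict[tuple[str, str], float] | None = None,
        singleton_exceptions: frozenset[str] = frozenset(),
    ):
        if module_ids is None:
            module_ids = [f"m{i}" for i in range(len(modules))]
        if len(module_ids) != len(modules):
            raise ValueError("module_ids/modules length mismatch")
        self.modules = list(modules)
        self.module_ids = list(module_ids)
        self.intra = intra or {}
        self.inter = inter or {}
        self.singleton_exceptions = singleton_exceptions

    def renamed(self, new_ids: list[str]) -> "ModuleSet":
        """Copy with module ids replaced positionally (scores keys remapped)."""
        if len(new_ids) != len(self.modules):
            raise ValueError("new_ids length mismatch")
        ren = dict(zip(self.module_ids, new_ids))
        return ModuleSet(
            self.modules,
            module_ids=list(new_ids),
            intra={ren[k]: v for k, v in self.intra.items()},
            inter={(ren[a], ren[b]): v for (a, b), v in self.inter.items()},
            singleton_exceptions=frozenset(ren[k] for k in self.singleton_exceptions),
        )

    def as_dict(self) -> dict[str, frozenset[str]]:
        return dict(zip(self.module_ids, self.modules))

    def membership(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for mid, members in zip(self.module_ids, self.modules):
            for node in members:
                out[node] = mid
        return out

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def covered(self) -> frozenset[str]:
        return frozenset().union(*self.modules) if self.modules else frozenset()


def symmetrize(pnet: ProximityNetwork) -> dict[tuple[str, str], float]:
    """Total association per unordered pair: prox(i,j) + prox(j,i)."""
    M = pnet.masked_matrix()
    S = M + M.T
    out: dict[tuple[str, str], float] = {}
    src, dst = np.nonzero(np.triu(S, k=1))
    for i, j in zip(src.tolist(), dst.tolist()):
        u, v = pnet.nodes[i], pnet.nodes[j]
        key = (u, v) if u <= v else (v, u)
        out[key] = float(S[i, j])
    return out


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def maximum_spanning_forest(
    weights: dict[tuple[str, str], float], nodes: frozenset[str] | set[str]
) -> Backbone:
    """Kruskal maximum-weight spanning forest with deterministic tie-breaks.

    Edges are taken in order of decreasing weight, ties broken by
    lexicographic endpoint order, so identical inputs always yield the same
    forest. Isolated nodes become single-node trees.
    """
    if any(w < 0 for w in weights.values()):
        raise ValueError("spanning forest requires non-negative weights")
    edges = sorted(
        ((u, v, w) for (u, v), w in weights.items()),
        key=lambda e: (-e[2], e[0], e[1]),
    )
    uf = _UnionFind(nodes)
    chosen: dict[str, list[tuple[str, str, float]]] = {}
    for u, v, w in edges:
        if uf.union(u, v):
            chosen.setdefault(u, []).append((u, v, w))
    # group nodes and edges by component root
    comp_nodes: dict[str, set[str]] = {}
    for node in nodes:
        comp_nodes.setdefault(uf.find(node), set()).add(node)
    comp_edges: dict[str, list[tuple[str, str, float]]] = {r: [] for r in comp_nodes}
    for bucket in chosen.values():
        for u, v, w in bucket:
            comp_edges[uf.find(u)].append((u, v, w))
    trees = [
        (frozenset(comp_nodes[r]), sorted(comp_edges[r]))
        for r in sorted(comp_nodes, key=str)
    ]
    return Backbone(trees=trees)


# -- divisive partitioning -------------------------------------------------


def _split_scores(P: np.ndarray, tin, tout, edges_child):
    """Intra/inter sums for every candidate cut of one rooted subtree.

    ``P`` is the thresholded proximity matrix restricted to and permuted into
    the subtree's DFS order, so every candidate module (the descendant set of
    a tree edge) is a contiguous index interval and all sums come from one
    2-D prefix-sum table in O(1) per edge.
    """
    m = P.shape[0]
    C = np.zeros((m + 1, m + 1))
    C[1:, 1:] = P.cumsum(0).cumsum(1)
    total = C[m, m]

    def box(a, b):  # sum of P over [a, b] x [a, b], inclusive DFS indices
        return C[b + 1, b + 1] - C[a, b + 1] - C[b + 1, a] + C[a, a]

    out = []
    for child in edges_child:
        a, b = tin[child], tout[child]
        intra_a = box(a, b)
        # rectangle sums across the cut come out of the remainder identity
        intra_b = total - intra_a - (C[b + 1, m] - C[a, m] - box(a, b)) - (
            C[m, b + 1] - C[m, a] - box(a, b)
        )
        inter = total - intra_a - intra_b
        out.append((intra_a, intra_b, inter))
    return out


def _dfs_order(adj: dict[int, list[int]], root: int):
    """Iterative DFS with children visited in sorted order (determinism)."""
    order: list[int] = []
    tin: dict[int, int] = {}
    tout: dict[int, int] = {}
    parent: dict[int, int] = {root: -1}
    stack: list[tuple[int, bool]] = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            tout[node] = len(order) - 1
            continue
        tin[node] = len(order)
        order.append(node)
        stack.append((node, True))
        for nb in sorted(adj[node], reverse=True):
            if nb != parent[node]:
                parent[nb] = node
                stack.append((nb, False))
    return order, tin, tout, parent


def partition(backbone: Backbone, pnet: ProximityNetwork) -> ModuleSet:
    """Partition a level's nodes by iterative admissible backbone cuts.

    Starting from one module per backbone tree, each step removes one tree
    link such that the ENTIRE resulting module set still satisfies the
    pairwise criterion: the two modules created by the cut must each cohere
    more strongly internally than with the cut sibling and with every other
    current module. (Existing modules need no re-check: a module that shrinks
    can only lose inter-module weight, so conditions involving untouched
    modules cannot newly fail.) Among admissible links the least significant
    one — smallest symmetrised backbone weight — is removed first, ties
    broken by smaller S_inter of the created pair, then lexicographic
    endpoints; the process stops when no admissible link remains. A final
    validation pass re-checks all pairs and merges violators (a safety net;
    the incremental invariant already guarantees the criterion).
    """
    if backbone.covered_nodes != frozenset(pnet.nodes):
        raise ValueError("backbone and proximity network node sets differ")
    Pfull = pnet.masked_matrix()
    node_index = {n: i for i, n in enumerate(pnet.nodes)}
    Psym = Pfull + Pfull.T
    n = Pfull.shape[0]

    # current modules: (sorted node list, tree edge list)
    mods: list[tuple[list[str], list[tuple[str, str, float]]]] = [
        (sorted(tree_nodes), tree_edges) for tree_nodes, tree_edges in backbone.trees
    ]

    while True:
        k = len(mods)
        Z = np.zeros((n, k))
        for a, (members, _) in enumerate(mods):
            Z[[node_index[u] for u in members], a] = 1.0
        R = Psym @ Z  # R[i, o]: total association of node i with module o
        best = None
        for cur, (nodes, edges) in enumerate(mods):
            if len(nodes) <= 1 or not edges:
                continue
            local = {u: i for i, u in enumerate(nodes)}
            adj: dict[int, list[int]] = {i: [] for i in range(len(nodes))}
            ew: dict[tuple[int, int], float] = {}
            for u, v, w in edges:
                iu, iv = local[u], local[v]
                adj[iu].append(iv)
                adj[iv].append(iu)
                ew[(iu, iv)] = ew[(iv, iu)] = w
            order, tin, tout, parent = _dfs_order(adj, 0)
            perm = [node_index[nodes[i]] for i in order]
            P = Pfull[np.ix_(perm, perm)]
            children = [i for i in range(len(nodes)) if parent.get(i, -1) != -1]
            scores = _split_scores(P, tin, tout, children)
            # per-candidate inter sums to every OTHER module via row prefixes
            # of R in DFS order
            cum = np.zeros((len(nodes) + 1, k))
            cum[1:] = R[perm].cumsum(axis=0)
            col_total = cum[-1]
            a_idx = np.array([tin[c] for c in children])
            b_idx = np.array([tout[c] for c in children])
            IV1 = cum[b_idx + 1] - cum[a_idx]  # (candidates, k)
            IV2 = col_total[None, :] - IV1
            others = np.ones(k, dtype=bool)
            others[cur] = False
            if others.any():
                max1 = IV1[:, others].max(axis=1)
                max2 = IV2[:, others].max(axis=1)
            else:
                max1 = max2 = np.full(len(children), -np.inf)
            sc = np.asarray(scores)  # columns: intra_a, intra_b, inter
            ok = (
                (sc[:, 0] > sc[:, 2])
                & (sc[:, 1] > sc[:, 2])
                & (sc[:, 0] > max1)
                & (sc[:, 1] > max2)
            )
            for ci in np.nonzero(ok)[0]:
                child = children[ci]
                u, v = nodes[child], nodes[parent[child]]
                # remove the least significant admissible link first: the
                # spanning forest adds weak inter-module bridges last, so
                # cutting the weakest links peels modules apart along their
                # natural boundaries
                key = (
                    ew[(local[u], local[v])],
                    sc[ci, 2],
                    min(u, v),
                    max(u, v),
                )
                if best is None or key < best[0]:
                    best = (key, cur, child, tin[child], tout[child], order)
        if best is None:
            break
        _, cur, child, a, b, order = best
        nodes, edges = mods[cur]
        side_a = {order[i] for i in range(a, b + 1)}
        nodes_a = [nodes[i] for i in sorted(side_a)]
        nodes_b = [nodes[i] for i in range(len(nodes)) if i not in side_a]
        set_a = set(nodes_a)
        edges_a = [e for e in edges if e[0] in set_a and e[1] in set_a]
        edges_b = [e for e in edges if e[0] not in set_a and e[1] not in set_a]
        mods[cur] = (nodes_a, edges_a)
        mods.append((nodes_b, edges_b))

    modules = _global_repair(
        [frozenset(members) for members, _ in mods], Pfull, node_index
    )
    return _score_modules(modules, Pfull, node_index)


def _pair_sums(modules: list[frozenset[str]], Pfull: np.ndarray, node_index):
    """Module-aggregated proximity sums M[a, b] = sum over a's rows, b's cols."""
    k = len(modules)
    n = Pfull.shape[0]
    Z = np.zeros((n, k))
    for a, members in enumerate(modules):
        for node in members:
            Z[node_index[node], a] = 1.0
    return Z.T @ Pfull @ Z


def _global_repair(modules, Pfull, node_index) -> list[frozenset[str]]:
    """Merge module pairs violating the pairwise criterion, smallest first.

    A pair with S_inter = 0 never violates: disconnected modules (different
    components of the thresholded graph) must not be merged. The aggregated
    sum matrix is collapsed in place as pairs merge, so the pass costs one
    dense aggregation plus vectorised scans.
    """
    modules = list(modules)
    M = _pair_sums(modules, Pfull, node_index)
    while len(modules) > 1:
        intra = np.diag(M).copy()
        inter = M + M.T
        np.fill_diagonal(inter, 0.0)
        ok = (intra[:, None] > inter) & (intra[None, :] > inter)
        viol = (inter > 0) & ~ok
        np.fill_diagonal(viol, False)
        if not viol.any():
            break
        severity = np.where(
            viol, inter - np.minimum(intra[:, None], intra[None, :]), np.inf
        )
        a, b = divmod(int(severity.argmin()), len(modules))
        if a > b:
            a, b = b, a
        M[a, :] += M[b, :]
        M[:, a] += M[:, b]
        M = np.delete(np.delete(M, b, axis=0), b, axis=1)
        modules[a] = modules[a] | modules[b]
        del modules[b]
    return modules


def _score_modules(modules, Pfull, node_index) -> ModuleSet:
    modules = sorted(modules, key=lambda m: sorted(m)[0])
    M = _pair_sums(modules, Pfull, node_index)
    ids = [f"m{i}" for i in range(len(modules))]
    intra = {ids[a]: float(M[a, a]) for a in range(len(modules))}
    inter = {}
    exceptions = set()
    for a in range(len(modules)):
        for b in range(a + 1, len(modules)):
            inter[(ids[a], ids[b])] = float(M[a, b] + M[b, a])
    for a in range(len(modules)):
        if intra[ids[a]] == 0.0:
            row_total = sum(
                inter[(ids[min(a, b)], ids[max(a, b)])]
                for b in range(len(modules))
                if b != a
            )
            if row_total == 0.0:
                exceptions.add(ids[a])
    return ModuleSet(
        modules,
        module_ids=ids,
        intra=intra,
        inter=inter,
        singleton_exceptions=frozenset(exceptions),
    )
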
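"""Reading and writing networks, partitions and pyramids.

All downstream modules operate on the in-memory types defined here. The
on-disk dialect is deliberately plain: whitespace-separated edge lists for
networks, two-column TSVs for memberships and annotations, and a single JSON
document for a full pyramid.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Iterable, Iterator
from pathlib import Path

import numpy as np

logger = logging.getLogger("pyramabs")

__all__ = [
    "WeightedNetwork",
    "read_edge_list",
    "write_edge_list",
    "read_membership",
    "write_pyramid",
    "read_pyramid",
    "read_annotations",
]


class WeightedNetwork:
    """A weighted, optionally directed network over named nodes.

    Node identifiers are opaque strings. Link weights are non-negative reals;
    an absent pair means weight zero, and self-links are never stored. For an
    undirected network both directions are stored symmetrically, so the
    adjacency matrix is symmetric.

    The adjacency is held densely, which is the right trade-off for the
    network sizes this tool targets (hundreds to a few thousand nodes).
    """

    def __init__(self, nodes: Iterable[str], directed: bool = False):
        self.nodes: tuple[str, ...] = tuple(dict.fromkeys(str(n) for n in nodes))
        self.directed = bool(directed)
        self._index = {n: i for i, n in enumerate(self.nodes)}
        self._A = np.zeros((len(self.nodes), len(self.nodes)), dtype=float)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        directed: bool = False,
        nodes: Iterable[str] | None = None,
    ) -> "WeightedNetwork":
        """Build a network from (source, target, weight) triples.

        Self-links are dropped with a warning; duplicate pairs have their
        weights summed (also warned, once per load).
        """
        edges = list(edges)
        if nodes is None:
            seen: dict[str, None] = {}
            for u, v, _ in edges:
                seen.setdefault(str(u))
                seen.setdefault(str(v))
            nodes = seen
        net = cls(nodes, directed=directed)
        A = net._A
        idx = net._index
        n_self = 0
        n_dup = 0
        for u, v, w in edges:
            w = float(w)
            if w < 0:
                raise ValueError(f"negative weight {w} on link {u!r} -> {v!r}")
            i, j = idx[str(u)], idx[str(v)]
            if i == j:
                n_self += 1
                continue
            if A[i, j] != 0.0:
                n_dup += 1
            A[i, j] += w
            if not directed:
                A[j, i] = A[i, j]
        if n_self:
            logger.warning("dropped %d self-link(s)", n_self)
        if n_dup:
            logger.warning("merged %d duplicate link(s) by summing weights", n_dup)
        return net

    @classmethod
    def from_adjacency(
        cls, A: np.ndarray, nodes: Iterable[str], directed: bool = False
    ) -> "WeightedNetwork":
        net = cls(nodes, directed=directed)
        A = np.asarray(A, dtype=float)
        if A.shape != (len(net.nodes), len(net.nodes)):
            raise ValueError("adjacency shape does not match node count")
        if (A < 0).any():
            raise ValueError("adjacency contains negative weights")
        A = A.copy()
        np.fill_diagonal(A, 0.0)
        if not directed and not np.allclose(A, A.T):
            raise ValueError("undirected network requires a symmetric adjacency")
        net._A = A
        return net

    # -- accessors --------------------------------------------------------

    @property
    def adjacency(self) -> np.ndarray:
        """Dense adjacency matrix A, rows = sources (read-only view)."""
        v = self._A.view()
        v.flags.writeable = False
        return v

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index(self, node: str) -> int:
        return self._index[node]

    def weight(self, u: str, v: str) -> float:
        return float(self._A[self._index[u], self._index[v]])

    def out_strength(self, u: str) -> float:
        """W_i^out: sum of weights of all outgoing links of node u."""
        return float(self._A[self._index[u]].sum())

    def links(self) -> Iterator[tuple[str, str, float]]:
        """Stored links as (source, target, weight) over ordered pairs."""
        src, dst = np.nonzero(self._A)
        for i, j in zip(src.tolist(), dst.tolist()):
            yield self.nodes[i], self.nodes[j], float(self._A[i, j])

    @property
    def n_links(self) -> int:
        """Number of stored links: ordered pairs if directed, unordered if not."""
        nz = int(np.count_nonzero(self._A))
        return nz if self.directed else nz // 2

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedNetwork):
            return NotImplemented
        if set(self.nodes) != set(other.nodes) or self.directed != other.directed:
            return False
        perm = [other._index[n] for n in self.nodes]
        return np.array_equal(self._A, other._A[np.ix_(perm, perm)])

    def __repr__(self) -> str:  # pragma: no cover
        kind = "directed" if self.directed else "undirected"
        return f"<WeightedNetwork {kind}, {self.n_nodes} nodes, {self.n_links} links>"


# -- edge lists -----------------------------------------------------------


def read_edge_list(
    path: str | Path, directed: bool = False, default_weight: float = 1.0
) -> WeightedNetwork:
    """Read a whitespace/tab-separated edge list.

    Each non-comment line is ``source target [weight]``; two-field lines get
    ``default_weight``. Lines starting with ``#`` and blank lines are skipped.
    Duplicate pairs are merged by summing weights, self-links dropped (both
    with a logged warning).
    """
    path = Path(path)
    edges: list[tuple[str, str, float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 2:
                u, v = parts
                w = float(default_weight)
            elif len(parts) == 3:
                u, v = parts[:2]
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: malformed weight {parts[2]!r}"
                    ) from exc
            else:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 or 3 fields, got {len(parts)}"
                )
            if w < 0:
                raise ValueError(f"{path}:{lineno}: negative weight {w}")
            edges.append((u, v, w))
    return WeightedNetwork.from_edges(edges, directed=directed)


def write_edge_list(net: WeightedNetwork, path: str | Path) -> None:
    """Write a network as a 3-column edge list (unordered pairs if undirected)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# source\ttarget\tweight\n")
        seen: set[tuple[str, str]] = set()
        for u, v, w in net.links():
            if not net.directed:
                key = (min(u, v), max(u, v))
                if key in seen:
                    continue
                seen.add(key)
            fh.write(f"{u}\t{v}\t{w:.10g}\n")


# -- memberships and annotations ------------------------------------------


def read_membership(path: str | Path) -> dict[str, str]:
    """Read a two-column node_id → module_id TSV (``#`` comments allowed)."""
    out: dict[str, str] = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields")
            out[parts[0]] = parts[1]
    return out


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a node_id → category_id TSV (one row per pair) into a mapping."""
    out: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields")
            out.setdefault(parts[0], set()).add(parts[1])
    return out


# -- pyramids -------------------------------------------------------------


def write_pyramid(pyramid, out_dir: str | Path) -> list[Path]:
    """Write a pyramid: per-level membership and abstract-network TSVs plus
    one JSON document with the full structure and run parameters.

    Levels are numbered as in the output convention where level 1 is the top;
    returns the list of files written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    n_levels = len(pyramid.levels)
    doc: dict = {"params": dict(pyramid.params), "stalled": pyramid.stalled, "levels": []}
    # pyramid.levels is bottom -> top; output numbering is 1 = top
    for depth, level in enumerate(reversed(pyramid.levels), start=1):
        mpath = out_dir / f"level{depth}_membership.tsv"
        with mpath.open("w") as fh:
            fh.write("# node_id\tmodule_id\n")
            for node in level.input_network.nodes:
                fh.write(f"{node}\t{level.parent_of[node]}\n")
        written.append(mpath)
        apath = out_dir / f"level{depth}_abstract_edges.tsv"
        write_edge_list(level.abstract_network, apath)
        written.append(apath)
        doc["levels"].append(
            {
                "level": depth,
                "n_nodes": level.input_network.n_nodes,
                "n_modules": len(level.module_set.modules),
                "modules": {
                    mid: sorted(members)
                    for mid, members in level.module_set.as_dict().items()
                },
                "abstract_edges": [
                    [u, v, w] for u, v, w in level.abstract_network.links()
                ],
                "parent_of": dict(level.parent_of),
            }
        )
    jpath = out_dir / "pyramid.json"
    jpath.write_text(json.dumps(doc, indent=1, sort_keys=True))
    written.append(jpath)
    return written


def read_pyramid(out_dir: str | Path):
    """Read back a pyramid written by :func:`write_pyramid`."""
    from .backbone_partition import ModuleSet
    from .pyramid import Pyramid, PyramidLevel

    doc = json.loads((Path(out_dir) / "pyramid.json").read_text())
    directed = bool(doc["params"].get("directed", False))
    levels: list[PyramidLevel] = []
    prev_abstract: WeightedNetwork | None = None
    for entry in reversed(doc["levels"]):  # stored top -> bottom
        modules = [frozenset(m) for m in entry["modules"].values()]
        module_ids = list(entry["modules"].keys())
        if prev_abstract is not None:
            input_net = prev_abstract
        else:
            # bottom level: the original input's links are not part of the
            # pyramid archive, only its node set is recoverable
            input_net = WeightedNetwork(sorted(entry["parent_of"]), directed=directed)
        abstract = WeightedNetwork.from_edges(
            [(u, v, w) for u, v, w in entry["abstract_edges"]],
            directed=True,  # stored pairs are explicit ordered pairs
            nodes=module_ids,
        )
        abstract.directed = directed
        prev_abstract = abstract
        levels.append(
            PyramidLevel(
                input_network=input_net,
                module_set=ModuleSet(modules, module_ids=module_ids),
                abstract_network=abstract,
                parent_of=dict(entry["parent_of"]),
            )
        )
    return Pyramid(levels=levels, params=doc["params"], stalled=doc["stalled"])
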
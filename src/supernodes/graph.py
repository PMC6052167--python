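"""Undirected graph container, edge-list I/O, k-cores and neighborhoods.

Graphs are simple (no self loops, at most one edge per unordered pair),
undirected, with strictly positive edge weights (1.0 for unweighted input).
Nodes are dense integers ``0..N-1``; original labels from an edge-list file
are kept in a side map so results can be written back in the caller's
vocabulary. The dense total order is what makes every tie-break downstream
(seed selection, growth claims) deterministic.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable
from typing import Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Graph",
    "ValidationError",
    "ParseError",
    "read_edgelist",
    "write_edgelist",
    "k_core",
    "neighborhood_within",
]


class ValidationError(ValueError):
    """A precondition or invariant was violated."""


class ParseError(ValueError):
    """An input file could not be parsed."""


class Graph:
    """Simple undirected weighted graph over nodes ``0..N-1``.

    Parameters
    ----------
    num_nodes
        Number of nodes ``N``; isolated nodes are allowed.
    edges
        Iterable of ``(u, v)`` or ``(u, v, weight)``; weight defaults to 1.0.
        Duplicate unordered pairs and self loops are rejected here — the
        edge-list reader applies its own collapsing rules before building.
    node_labels
        Optional original labels, index = dense node id.
    """

    def __init__(
        self,
        num_nodes: int,
        edges: Iterable[tuple] = (),
        node_labels: Sequence | None = None,
    ):
        if num_nodes < 0:
            raise ValidationError("num_nodes must be non-negative")
        g = nx.Graph()
        g.add_nodes_from(range(num_nodes))
        for e in edges:
            if len(e) == 2:
                u, v = e
                w = 1.0
            else:
                u, v, w = e
            u, v, w = int(u), int(v), float(w)
            if u == v:
                raise ValidationError(f"self loop at node {u}")
            if not (0 <= u < num_nodes and 0 <= v < num_nodes):
                raise ValidationError(f"edge ({u},{v}) out of range 0..{num_nodes - 1}")
            if w <= 0:
                raise ValidationError(f"non-positive weight {w} on edge ({u},{v})")
            if g.has_edge(u, v):
                raise ValidationError(f"duplicate edge ({u},{v})")
            g.add_edge(u, v, weight=w)
        self._nx = g
        if node_labels is not None and len(node_labels) != num_nodes:
            raise ValidationError("node_labels length must equal num_nodes")
        self.node_labels = list(node_labels) if node_labels is not None else None

    # -- basic accessors -------------------------------------------------

    @property
    def num_nodes(self) -> int:
        return self._nx.number_of_nodes()

    @property
    def num_edges(self) -> int:
        return self._nx.number_of_edges()

    @property
    def total_weight(self) -> float:
        """Sum of edge weights (the M' of weighted modularity)."""
        return float(self._nx.size(weight="weight"))

    def edges(self) -> list[tuple[int, int, float]]:
        """Edges as ``(u, v, weight)`` with ``u < v``, sorted."""
        out = [
            (min(u, v), max(u, v), float(d["weight"]))
            for u, v, d in self._nx.edges(data=True)
        ]
        out.sort()
        return out

    def degrees(self) -> np.ndarray:
        """Unweighted degree (edge count) per node."""
        d = np.zeros(self.num_nodes, dtype=np.int64)
        for node, deg in self._nx.degree():
            d[node] = deg
        return d

    def strengths(self) -> np.ndarray:
        """Weighted degree d_i = sum of incident edge weights."""
        s = np.zeros(self.num_nodes, dtype=float)
        for node, deg in self._nx.degree(weight="weight"):
            s[node] = deg
        return s

    def neighbors(self, i: int) -> dict[int, float]:
        """Neighbors of ``i`` mapped to the connecting edge weight."""
        self._check_node(i)
        return {j: float(d["weight"]) for j, d in self._nx[i].items()}

    def has_edge(self, u: int, v: int) -> bool:
        return self._nx.has_edge(u, v)

    def is_unweighted(self) -> bool:
        return all(d["weight"] == 1.0 for _, _, d in self._nx.edges(data=True))

    def to_networkx(self) -> nx.Graph:
        """The underlying networkx graph (treat as read-only)."""
        return self._nx

    def label_of(self, i: int):
        return self.node_labels[i] if self.node_labels is not None else i

    def id_of(self, label) -> int:
        """Dense node id for an original label (identity when unlabelled)."""
        if self.node_labels is None:
            i = int(label)
            self._check_node(i)
            return i
        if not hasattr(self, "_label_index"):
            self._label_index = {str(lab): i for i, lab in enumerate(self.node_labels)}
        try:
            return self._label_index[str(label)]
        except KeyError:
            raise ValidationError(f"unknown node label {label!r}") from None

    def _check_node(self, i: int) -> None:
        if not (0 <= int(i) < self.num_nodes):
            raise ValidationError(f"node {i} out of range 0..{self.num_nodes - 1}")

    def __repr__(self) -> str:  # pragma: no cover
        return f"Graph(N={self.num_nodes}, M={self.num_edges})"

    def __eq__(self, other) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return self.num_nodes == other.num_nodes and self.edges() == other.edges()

    def labeled_edges(self) -> set[tuple]:
        """Edge set on original labels, for round-trip comparisons."""
        out = set()
        for u, v, w in self.edges():
            a, b = self.label_of(u), self.label_of(v)
            key = tuple(sorted((str(a), str(b))))
            out.add((key[0], key[1], w))
        return out


# -- edge-list I/O --------------------------------------------------------


def read_edgelist(path, weighted: bool = False) -> Graph:
    """Read a whitespace-delimited edge list into a dense-id :class:`Graph`.

    Each non-comment line holds two node labels, plus a weight when
    ``weighted``. Labels may be arbitrary strings; they are densified to
    ``0..N-1`` in first-appearance order. Duplicate unordered edges are
    collapsed (weights summed when weighted, deduplicated otherwise) and
    self loops are dropped with a logged count.
    """
    index: dict[str, int] = {}
    labels: list[str] = []
    weights: dict[tuple[int, int], float] = {}
    n_self = 0

    def node_id(tok: str) -> int:
        if tok not in index:
            index[tok] = len(labels)
            labels.append(tok)
        return index[tok]

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            want = 3 if weighted else 2
            if len(toks) != want:
                raise ParseError(
                    f"{path}: line {lineno}: expected {want} fields, got {len(toks)}"
                )
            if weighted:
                try:
                    w = float(toks[2])
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: bad weight {toks[2]!r}") from exc
                if w < 0:
                    raise ValidationError(f"{path}: line {lineno}: negative weight {w}")
                if w == 0:
                    raise ValidationError(f"{path}: line {lineno}: zero weight")
            else:
                w = 1.0
            u, v = node_id(toks[0]), node_id(toks[1])
            if u == v:
                n_self += 1
                continue
            key = (min(u, v), max(u, v))
            if key in weights:
                if weighted:
                    weights[key] += w
            else:
                weights[key] = w
    if n_self:
        logger.info("read_edgelist(%s): dropped %d self loop(s)", path, n_self)
    return Graph(
        len(labels),
        [(u, v, w) for (u, v), w in sorted(weights.items())],
        node_labels=labels,
    )


def write_edgelist(g: Graph, path, weighted: bool = False) -> None:
    """Write one line per unordered edge, endpoints ascending by dense id,
    lines sorted — deterministic output. Original labels are emitted when the
    graph carries them. Isolated nodes are not representable in a bare edge
    list; a warning is logged if any exist.
    """
    deg = g.degrees()
    if g.num_nodes and int((deg == 0).sum()):
        logger.warning(
            "write_edgelist: %d isolated node(s) not representable in an edge list",
            int((deg == 0).sum()),
        )
    with open(path, "w") as fh:
        for u, v, w in g.edges():
            if weighted:
                wtxt = format(w, "g")
                fh.write(f"{g.label_of(u)}\t{g.label_of(v)}\t{wtxt}\n")
            else:
                fh.write(f"{g.label_of(u)}\t{g.label_of(v)}\n")


# -- k-core and neighborhoods ---------------------------------------------


def k_core(g: Graph, k: int) -> set[int]:
    """Maximal node set whose induced subgraph has minimum degree ``k``.

    Degree counts edges, ignoring weights. The result may span several
    connected components and may be empty. Computed by iterated pruning of
    nodes of degree < k (via networkx core numbers).
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if g.num_nodes == 0:
        return set()
    core_num = nx.core_number(g.to_networkx())
    return {n for n, c in core_num.items() if c >= k}


def neighborhood_within(g: Graph, i: int, o: int) -> set[int]:
    """All nodes at shortest-path distance 1..o from node ``i`` (BFS)."""
    g._check_node(i)
    if o < 1:
        raise ValidationError("o must be >= 1")
    dist = nx.single_source_shortest_path_length(g.to_networkx(), int(i), cutoff=o)
    dist.pop(int(i), None)
    return set(dist)
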
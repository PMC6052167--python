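"""Grow super nodes around seeds, build the compressed network, lift back.

A super node is a connected patch of original nodes agglomerated around one
seed. Growth proceeds in synchronous rounds (BFS layers): in round r every
still-unassigned node with at least one assigned neighbor joins a super
node, judged against the assignment state at the *start* of the round, so
the result is independent of node iteration order. A node adjacent to
several super nodes joins the one to which it has the greatest total edge
weight; remaining ties go to the super node whose seed was selected
earliest. Nodes still unassigned after ``o_max`` rounds form the periphery.

The super-node network W has one node per super node and, between two
distinct super nodes, an edge weighted by the total weight of original
edges crossing between their member sets. Within-super-node edges are
dropped (no self loops) and edges touching the periphery are dropped — the
periphery is not used to build W.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph import Graph, ValidationError

logger = logging.getLogger(__name__)

PERIPHERY = -1
"""Sentinel value for nodes left unassigned after o_max growth rounds."""

__all__ = [
    "PERIPHERY",
    "SuperNodeAssignment",
    "SuperNodeNetwork",
    "grow_supernodes",
    "build_supernode_network",
    "lift_partition",
    "read_assignment",
    "write_assignment",
]


@dataclass
class SuperNodeAssignment:
    """Node-to-super-node map ``s`` of length N.

    ``assignment[i]`` is a super-node index in ``0..S-1`` (the index equals
    the seed's selection rank) or :data:`PERIPHERY`.
    """

    assignment: np.ndarray
    seed_of: list[int]
    o_max: int

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=np.int64)
        s = len(self.seed_of)
        vals = self.assignment
        if vals.ndim != 1:
            raise ValidationError("assignment must be a 1-d vector")
        bad = (vals != PERIPHERY) & ((vals < 0) | (vals >= s))
        if bad.any():
            raise ValidationError("assignment values must be in 0..S-1 or PERIPHERY")
        for j, seed in enumerate(self.seed_of):
            if vals[seed] != j:
                raise ValidationError(f"seed {seed} not assigned to its super node {j}")

    @property
    def num_supernodes(self) -> int:
        return len(self.seed_of)

    @property
    def num_nodes(self) -> int:
        return len(self.assignment)

    def periphery_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.assignment == PERIPHERY)

    def membership_sets(self) -> list[set[int]]:
        out: list[set[int]] = [set() for _ in range(self.num_supernodes)]
        for i, j in enumerate(self.assignment):
            if j != PERIPHERY:
                out[j].add(i)
        return out

    def coverage(self) -> float:
        """Fraction of nodes assigned to some super node."""
        return float((self.assignment != PERIPHERY).mean())


@dataclass
class SuperNodeNetwork:
    """Weighted network W over super nodes plus the map back to originals."""

    graph: Graph
    membership: list[set[int]]
    periphery: set[int] = field(default_factory=set)

    @property
    def num_supernodes(self) -> int:
        return self.graph.num_nodes


def grow_supernodes(g: Graph, seeds: list[int], o_max: int = 6) -> SuperNodeAssignment:
    """Agglomerate nodes around ``seeds`` in up to ``o_max`` synchronous rounds."""
    if len(seeds) == 0:
        raise ValidationError("seed set must be non-empty")
    if o_max < 1:
        raise ValidationError("o_max must be >= 1")
    if len(set(seeds)) != len(seeds):
        raise ValidationError("seed ids must be distinct")
    for s in seeds:
        g._check_node(s)

    n = g.num_nodes
    assignment = np.full(n, PERIPHERY, dtype=np.int64)
    for rank, s in enumerate(seeds):
        assignment[s] = rank

    unassigned = {i for i in range(n) if assignment[i] == PERIPHERY}
    for _ in range(o_max):
        if not unassigned:
            break
        claims: list[tuple[int, int]] = []
        for i in unassigned:
            # total edge weight from i to each super node under the
            # start-of-round assignment
            totals: dict[int, float] = {}
            for j, w in g.neighbors(i).items():
                sj = assignment[j]
                if sj != PERIPHERY:
                    totals[sj] = totals.get(sj, 0.0) + w
            if totals:
                best = min(totals, key=lambda s_: (-totals[s_], s_))
                claims.append((i, best))
        if not claims:
            break
        for i, s_ in claims:
            assignment[i] = s_
            unassigned.discard(i)

    if unassigned:
        comp_no_seed = sum(
            1
            for comp in nx.connected_components(g.to_networkx())
            if all(assignment[v] == PERIPHERY for v in comp)
        )
        if comp_no_seed:
            logger.warning(
                "grow_supernodes: %d connected component(s) contain no seed; "
                "their nodes fall in the periphery",
                comp_no_seed,
            )
        logger.info(
            "grow_supernodes: %d node(s) unassigned after o_max=%d rounds (periphery)",
            len(unassigned),
            o_max,
        )
    return SuperNodeAssignment(assignment, list(seeds), o_max)


def build_supernode_network(g: Graph, s: SuperNodeAssignment) -> SuperNodeNetwork:
    """Aggregate ``g`` into the weighted super-node network W.

    Edge weights are sums of original edge weights crossing two distinct
    super nodes (counts when ``g`` is unweighted). Within-super-node edges
    and periphery-touching edges are dropped. Super nodes with no crossing
    edge remain as isolated nodes of W.
    """
    if s.num_nodes != g.num_nodes:
        raise ValidationError("assignment length does not match graph size")
    a = s.assignment
    weights: dict[tuple[int, int], float] = {}
    for u, v, w in g.edges():
        su, sv = int(a[u]), int(a[v])
        if su == PERIPHERY or sv == PERIPHERY or su == sv:
            continue
        key = (min(su, sv), max(su, sv))
        weights[key] = weights.get(key, 0.0) + w
    wg = Graph(
        s.num_supernodes,
        [(u, v, w) for (u, v), w in sorted(weights.items())],
    )
    return SuperNodeNetwork(
        graph=wg,
        membership=s.membership_sets(),
        periphery=set(int(i) for i in s.periphery_nodes()),
    )


def lift_partition(s: SuperNodeAssignment, z_sn) -> np.ndarray:
    """Map a super-node partition back to the original N nodes (z^SN).

    Every node inherits its super node's community label; all periphery
    nodes share one fresh label distinct from every super-node community.
    """
    z_sn = np.asarray(z_sn, dtype=np.int64)
    if z_sn.ndim != 1 or len(z_sn) != s.num_supernodes:
        raise ValidationError(
            f"super-node partition length {len(z_sn)} != number of super nodes "
            f"{s.num_supernodes}"
        )
    lifted = np.empty(s.num_nodes, dtype=np.int64)
    assigned = s.assignment != PERIPHERY
    lifted[assigned] = z_sn[s.assignment[assigned]]
    if (~assigned).any():
        lifted[~assigned] = z_sn.max() + 1 if len(z_sn) else 0
    return lifted


def write_assignment(s: SuperNodeAssignment, path, labels=None) -> None:
    """Two columns ``node_id supernode_id``; periphery written as -1."""
    with open(path, "w") as fh:
        for i, j in enumerate(s.assignment):
            key = labels[i] if labels is not None else i
            fh.write(f"{key}\t{int(j)}\n")


def read_assignment(path, o_max: int = 6) -> SuperNodeAssignment:
    pairs: dict[int, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            i, j = line.split()
            pairs[int(i)] = int(j)
    n = max(pairs) + 1 if pairs else 0
    assignment = np.full(n, PERIPHERY, dtype=np.int64)
    for i, j in pairs.items():
        assignment[i] = j
    num_sn = int(assignment.max()) + 1 if (assignment != PERIPHERY).any() else 0
    # reconstruct seed_of as the lowest node id of each super node; ranks are
    # preserved by the file's supernode indices
    seed_of = []
    for j in range(num_sn):
        members = np.flatnonzero(assignment == j)
        if len(members) == 0:
            raise ValidationError(f"{path}: super node {j} has no members")
        seed_of.append(int(members[0]))
    return SuperNodeAssignment(assignment, seed_of, o_max)
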
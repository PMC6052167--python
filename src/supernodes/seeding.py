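"""Seed selection for super-node centers.

Seeds should be central, good at collapsing the network, and well separated.
Two strategies are provided: plain highest-degree selection, and CoreHD —
repeatedly take the highest-degree node *of the current 2-core*, remove it,
and recompute the 2-core. CoreHD comes from the network dismantling /
decycling literature, where deleting high-degree core nodes rapidly breaks
the graph into small components; here that same property spreads seeds
across the network instead of piling them into one hub cluster.

All tie-breaks go to the lowest node id, so seeding is fully deterministic.
External seeders (e.g. Slashburn orderings) are supported by reading a seed
list file rather than being reimplemented.
"""

from __future__ import annotations

import networkx as nx

from .graph import Graph, ValidationError

__all__ = [
    "corehd_seeds",
    "highest_degree_seeds",
    "seed_jaccard",
    "read_seed_list",
    "write_seed_list",
]


def _check_s(g: Graph, num_seeds: int) -> None:
    if num_seeds < 1:
        raise ValidationError("number of seeds must be >= 1")
    if num_seeds > g.num_nodes:
        raise ValidationError(
            f"number of seeds {num_seeds} exceeds number of nodes {g.num_nodes}"
        )


def _argmax_degree(h: nx.Graph, nodes) -> int:
    """Highest-degree node among ``nodes`` in ``h``; ties -> lowest id."""
    best = None
    best_key = None
    for n in nodes:
        key = (-h.degree(n), n)
        if best_key is None or key < best_key:
            best, best_key = n, key
    return best


def corehd_seeds(g: Graph, num_seeds: int) -> list[int]:
    """Select ``num_seeds`` seeds by CoreHD, in selection order.

    Each round: recompute the 2-core of the working graph; pick its
    highest-degree node (degree measured inside the induced 2-core,
    ties -> lowest id); delete that node and its edges. If the 2-core
    empties before enough seeds are found, fall back to highest-degree
    selection on the residual graph (still with sequential removal), so a
    forest degenerates gracefully and ``num_seeds`` seeds always exist.
    """
    _check_s(g, num_seeds)
    work = g.to_networkx().copy()
    seeds: list[int] = []
    for _ in range(num_seeds):
        core_num = nx.core_number(work)
        core = [n for n, c in core_num.items() if c >= 2]
        if core:
            sub = work.subgraph(core)
            pick = _argmax_degree(sub, core)
        else:
            pick = _argmax_degree(work, work.nodes)
        seeds.append(pick)
        work.remove_node(pick)
    return seeds


def highest_degree_seeds(g: Graph, num_seeds: int) -> list[int]:
    """The ``num_seeds`` highest-degree nodes, ranked by (-degree, id).

    No removal or recomputation — the O(M) baseline strategy.
    """
    _check_s(g, num_seeds)
    deg = g.degrees()
    order = sorted(range(g.num_nodes), key=lambda n: (-int(deg[n]), n))
    return order[:num_seeds]


def seed_jaccard(a, b) -> float:
    """Jaccard similarity |a ∩ b| / |a ∪ b| between two seed sets."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise ValidationError("seed sets must be non-empty")
    return len(sa & sb) / len(sa | sb)


def read_seed_list(path) -> list[int]:
    """One node id per line, selection order top to bottom."""
    seeds: list[int] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            seeds.append(int(line))
    if len(set(seeds)) != len(seeds):
        raise ValidationError(f"{path}: duplicate seed ids")
    return seeds


def write_seed_list(seeds, path, labels=None) -> None:
    with open(path, "w") as fh:
        for s in seeds:
            key = labels[s] if labels is not None else int(s)
            fh.write(f"{key}\n")
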
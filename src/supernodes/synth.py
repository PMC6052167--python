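"""Seeded generators of graphs with planted community structure.

These stand in for real network datasets in tests and experiments: a
planted-partition (equal-probability stochastic block model) graph whose
truth labels are known by construction, and a ring of cliques whose
community structure is unambiguous. Both are deterministic given their
parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph import Graph, ValidationError

__all__ = ["PlantedGraphBundle", "planted_partition_graph", "ring_of_cliques"]


@dataclass
class PlantedGraphBundle:
    """A synthetic graph together with its planted truth partition."""

    graph: Graph
    truth: np.ndarray
    params: dict


def block_sizes(n: int, k: int) -> list[int]:
    """Near-equal block sizes: the first ``n mod k`` blocks get one extra node."""
    base, extra = divmod(n, k)
    return [base + (1 if j < extra else 0) for j in range(k)]


def planted_partition_graph(
    n: int, k: int, p_in: float, p_out: float, rng_seed: int = 0
) -> PlantedGraphBundle:
    """Assortative planted-partition graph with K near-equal blocks.

    Within-block node pairs are joined independently with probability
    ``p_in``, cross-block pairs with ``p_out`` (requires p_in > p_out). Block
    j holds the contiguous id range given by :func:`block_sizes`, so the
    truth partition is reproducible from (n, k) alone.
    """
    if k < 1 or k > n:
        raise ValidationError("need 1 <= k <= n")
    if not (0 < p_in <= 1) or not (0 <= p_out < 1):
        raise ValidationError("need p_in in (0,1] and p_out in [0,1)")
    if p_in <= p_out:
        raise ValidationError("assortative fixture requires p_in > p_out")
    sizes = block_sizes(n, k)
    probs = np.full((k, k), p_out)
    np.fill_diagonal(probs, p_in)
    g_nx = nx.stochastic_block_model(
        sizes, probs.tolist(), seed=int(rng_seed), selfloops=False
    )
    edges = [(u, v) for u, v in g_nx.edges()]
    truth = np.repeat(np.arange(k), sizes)
    graph = Graph(n, edges)
    return PlantedGraphBundle(
        graph=graph,
        truth=truth,
        params={"n": n, "K": k, "p_in": p_in, "p_out": p_out, "rng_seed": int(rng_seed)},
    )


def ring_of_cliques(k: int, c: int) -> PlantedGraphBundle:
    """``k`` cliques of size ``c`` joined in a ring by single bridge edges.

    Clique j occupies ids ``j*c .. j*c + c - 1``; its bridge node is its
    lowest id, connected to the bridge node of clique ``(j+1) mod k``. The
    edge count is exactly k*c*(c-1)/2 + k.
    """
    if k < 3 or c < 3:
        raise ValidationError("need k >= 3 cliques of size c >= 3")
    edges: list[tuple[int, int]] = []
    for j in range(k):
        base = j * c
        members = range(base, base + c)
        edges.extend(
            (u, v) for ui, u in enumerate(members) for v in list(members)[ui + 1 :]
        )
        edges.append((base, ((j + 1) % k) * c))
    truth = np.repeat(np.arange(k), c)
    return PlantedGraphBundle(
        graph=Graph(k * c, sorted(set(tuple(sorted(e)) for e in edges))),
        truth=truth,
        params={"k": k, "c": c},
    )
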
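"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (from-scratch recomputation, full
enumeration, all-pairs statistics) and shares no code path with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# -- k-core / CoreHD ---------------------------------------------------------


def pruning_k_core(num_nodes: int, edges, k: int) -> set[int]:
    """k-core by literal iterated pruning of nodes with degree < k."""
    adj = {i: set() for i in range(num_nodes)}
    for u, v, *_ in edges:
        adj[u].add(v)
        adj[v].add(u)
    alive = set(range(num_nodes))
    changed = True
    while changed:
        changed = False
        for i in list(alive):
            if len(adj[i] & alive) < k:
                alive.discard(i)
                changed = True
    return alive


def naive_corehd(num_nodes: int, edges, num_seeds: int) -> list[int]:
    """CoreHD with a from-scratch 2-core recomputation after every removal."""
    adj = {i: set() for i in range(num_nodes)}
    for u, v, *_ in edges:
        adj[u].add(v)
        adj[v].add(u)
    alive = set(range(num_nodes))
    seeds = []
    for _ in range(num_seeds):
        core = pruning_k_core(
            num_nodes,
            [(u, v) for u in alive for v in adj[u] if u < v and v in alive],
            2,
        )
        pool = core if core else alive
        pick = min(pool, key=lambda n: (-len(adj[n] & pool), n))
        seeds.append(pick)
        alive.discard(pick)
    return seeds


# -- partitions and modularity ------------------------------------------------


def set_partitions(items):
    """All set partitions of ``items`` (restricted growth strings)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1 :]
        yield [[first]] + smaller


def brute_force_best_modularity(num_nodes, edges, gamma=1.0):
    """Exhaustive modularity maximum over all partitions (tiny n only)."""
    strengths = np.zeros(num_nodes)
    m = 0.0
    for u, v, w in edges:
        strengths[u] += w
        strengths[v] += w
        m += w
    best_q, best_parts = -np.inf, None

    def q_of(blocks):
        q = 0.0
        for block in blocks:
            bs = set(block)
            w_in = sum(w for u, v, w in edges if u in bs and v in bs)
            d_c = strengths[list(bs)].sum()
            q += w_in / m - gamma * (d_c / (2 * m)) ** 2
        return q

    for blocks in set_partitions(range(num_nodes)):
        q = q_of(blocks)
        if q > best_q + 1e-12:
            best_q, best_parts = q, blocks
    return best_q, best_parts


# -- SBM likelihood ------------------------------------------------------------


def brute_force_sbm_loglik(num_nodes, edges, z, pi) -> float:
    """Bernoulli likelihood as a literal product over unordered node pairs."""
    present = {(min(u, v), max(u, v)) for u, v, *_ in edges}
    ll = 0.0
    for i, j in itertools.combinations(range(num_nodes), 2):
        p = pi[z[i]][z[j]]
        a = 1 if (i, j) in present else 0
        term = p if a else 1.0 - p
        if term == 0.0:
            return float("-inf")
        if term != 1.0:
            ll += math.log(term)
    return ll


# -- NMI -----------------------------------------------------------------------


def entropy_nmi(z_a, z_b) -> float:
    """Mutual information normalized by the arithmetic mean of entropies."""
    z_a, z_b = np.asarray(z_a), np.asarray(z_b)
    n = len(z_a)
    _, ia = np.unique(z_a, return_inverse=True)
    _, ib = np.unique(z_b, return_inverse=True)
    joint = np.zeros((ia.max() + 1, ib.max() + 1))
    np.add.at(joint, (ia, ib), 1.0)
    joint /= n
    pa, pb = joint.sum(axis=1), joint.sum(axis=0)

    def entropy(p):
        p = p[p > 0]
        return -np.sum(p * np.log(p))

    h_a, h_b = entropy(pa), entropy(pb)
    nz = joint > 0
    mi = np.sum(joint[nz] * np.log(joint[nz] / np.outer(pa, pb)[nz]))
    if h_a + h_b == 0:
        return 1.0
    return float(2.0 * mi / (h_a + h_b))


# -- AUC ------------------------------------------------------------------------


def all_pairs_auc(y, scores) -> float:
    """AUC as the fraction of (positive, negative) pairs ranked correctly,
    ties counting one half."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return float(wins / (len(pos) * len(neg)))


# -- random graphs ---------------------------------------------------------------


def random_er_edges(num_nodes, p, rng):
    """Erdos-Renyi edge list with unit weights."""
    edges = []
    for i in range(num_nodes):
        for j in range(i + 1, num_nodes):
            if rng.random() < p:
                edges.append((i, j, 1.0))
    return edges
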
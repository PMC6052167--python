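"""Partition-quality and partition-similarity statistics.

Two quantities judge a super-node representation. Under-segmentation error

    U = (1/K) sum_k ( [sum over super nodes s_j touching community k of |s_j|]
                      - |k| ) / |k|

measures how badly super nodes bleed across the community boundaries of a
reference partition: U = 0 exactly when every super node is contained in a
single community. Normalized mutual information between two partitions,

    NMI = -2 sum_ij N_ij log(N_ij N / (N_i. N_.j))
          / [ sum_i N_i. log(N_i./N) + sum_j N_.j log(N_.j/N) ],

computed from their contingency table, compares community structure up to
relabeling (1 = identical, 0 = independent). The normalization is the
arithmetic mean of the two label entropies; the logarithm base cancels and
is taken natural here.

A permutation baseline (shuffle which node carries which label, preserving
community sizes) calibrates what NMI chance agreement looks like.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compression import PERIPHERY, SuperNodeAssignment
from .graph import ValidationError

__all__ = [
    "ContingencyTable",
    "contingency_table",
    "nmi",
    "under_segmentation_error",
    "permutation_nmi_baseline",
]


@dataclass
class ContingencyTable:
    """R x C cross-tabulation of two label vectors over the same nodes."""

    counts: np.ndarray
    row_labels: np.ndarray
    col_labels: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def _as_labels(z) -> np.ndarray:
    z = np.asarray(z)
    if z.ndim != 1:
        raise ValidationError("partition must be a 1-d label vector")
    return z


def contingency_table(z_a, z_b) -> ContingencyTable:
    """counts[i][j] = number of nodes with label i in ``z_a`` and j in ``z_b``."""
    z_a, z_b = _as_labels(z_a), _as_labels(z_b)
    if len(z_a) != len(z_b):
        raise ValidationError("partitions must have equal length")
    rows, ra = np.unique(z_a, return_inverse=True)
    cols, rb = np.unique(z_b, return_inverse=True)
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    np.add.at(counts, (ra, rb), 1)
    return ContingencyTable(counts, rows, cols)


def nmi(z_a, z_b) -> float:
    """Normalized mutual information between two partitions, in [0, 1].

    Degenerate case: when both partitions are single-community the
    denominator vanishes; the partitions are then identical trivial
    partitions and the value is 1.0 by convention. One trivial vs one
    non-trivial yields 0 naturally (zero numerator, non-zero denominator).
    """
    table = contingency_table(z_a, z_b)
    counts = table.counts.astype(float)
    n = counts.sum()
    if n < 1:
        raise ValidationError("partitions must be non-empty")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    denom = float(np.sum(row * np.log(row / n)) + np.sum(col * np.log(col / n)))
    if denom == 0.0:
        return 1.0
    nz = counts > 0
    outer = np.outer(row, col)
    num = -2.0 * float(np.sum(counts[nz] * np.log(counts[nz] * n / outer[nz])))
    return num / denom


def _membership_sets(s, include_periphery: bool) -> list[set[int]]:
    """Accept a SuperNodeAssignment or an explicit list of node sets."""
    if isinstance(s, SuperNodeAssignment):
        sets = s.membership_sets()
        periphery = set(int(i) for i in s.periphery_nodes())
        if include_periphery and periphery:
            sets = sets + [periphery]
        return sets
    return [set(m) for m in s]


def under_segmentation_error(s, z_full, include_periphery: bool = True) -> float:
    """Under-segmentation error U of super nodes against a reference partition.

    ``s`` is a :class:`~supernodes.compression.SuperNodeAssignment` or an
    explicit list of membership node-sets. By default the periphery (if any)
    participates as one additional super node; set ``include_periphery``
    False to leave periphery nodes out of every super node (they still count
    toward community sizes).
    """
    z_full = _as_labels(z_full)
    sets = _membership_sets(s, include_periphery)
    labels = np.unique(z_full)
    total = 0.0
    for lab in labels:
        community = set(np.flatnonzero(z_full == lab))
        size_k = len(community)
        if size_k == 0:
            raise ValidationError("empty community in reference partition")
        union = sum(len(sj) for sj in sets if sj & community)
        total += (union - size_k) / size_k
    return total / len(labels)


def permutation_nmi_baseline(
    z_full, z_sn, n_perm: int = 1000, rng_seed: int = 0
) -> tuple[float, float]:
    """Mean and sd of NMI(z_full, permuted z_sn) over label permutations.

    Each permutation shuffles which node carries which existing label of
    ``z_sn``, preserving all community sizes; the resulting NMI distribution
    is the chance-agreement baseline against which observed NMI values are
    judged.
    """
    z_full, z_sn = _as_labels(z_full), _as_labels(z_sn)
    if len(z_full) != len(z_sn):
        raise ValidationError("partitions must have equal length")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(int(rng_seed))
    vals = np.empty(n_perm)
    for p in range(n_perm):
        vals[p] = nmi(z_full, rng.permutation(z_sn))
    return float(vals.mean()), float(vals.std())
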
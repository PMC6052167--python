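"""Experiment harness: local-agreement AUC, quality curves, variability.

Three experiment families probe a super-node representation:

* **Local agreement** — given a partition z and the full network, score each
  node's probability of belonging to community k as the fraction of its
  order-o neighborhood carrying label k, then run a per-community binary
  ROC (sweeping the probability threshold) and report the minimum AUC
  across communities. High min-AUC means even the worst community agrees
  with local connectivity.
* **Quality curves** — vary the number of super nodes S and record
  NMI(z_full, z_sn) and the under-segmentation error per replicate.
* **Variability** — repeated detector runs on one representation (full or
  compressed-and-lifted) compared pairwise by NMI, within one detector and
  across detector pairs.

Results are tidy pandas DataFrames, one record per measurement, each
carrying the RNG seed that produced it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .compression import build_supernode_network, grow_supernodes, lift_partition
from .detection import densify_labels, get_detector
from .graph import Graph, ValidationError, neighborhood_within
from .metrics import nmi, under_segmentation_error
from .rng import derive_seed
from .seeding import corehd_seeds

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityScoreMatrix",
    "neighbor_community_scores",
    "min_community_auc",
    "quality_curve",
    "variability_matrix",
    "summarize",
]


@dataclass
class CommunityScoreMatrix:
    """Per-node community probabilities from order-o neighborhood composition.

    Rows of scorable nodes sum to 1; nodes with an empty order-o
    neighborhood get an all-zero row and ``scorable[i] = False``.
    """

    scores: np.ndarray
    order: int
    scorable: np.ndarray

    @property
    def coverage(self) -> float:
        return float(self.scorable.mean())


def neighbor_community_scores(g: Graph, z, o: int = 1) -> CommunityScoreMatrix:
    """score[i][k] = fraction of nodes within distance o of i labelled k."""
    if o < 1:
        raise ValidationError("o must be >= 1")
    z = densify_labels(z)
    if len(z) != g.num_nodes:
        raise ValidationError("partition length does not match graph")
    k = int(z.max()) + 1
    n = g.num_nodes
    scores = np.zeros((n, k))
    scorable = np.zeros(n, dtype=bool)
    for i in range(n):
        nbhd = neighborhood_within(g, i, o)
        if not nbhd:
            continue
        scorable[i] = True
        counts = np.bincount(z[list(nbhd)], minlength=k)
        scores[i] = counts / counts.sum()
    return CommunityScoreMatrix(scores=scores, order=o, scorable=scorable)


def min_community_auc(g: Graph, z, o: int = 1) -> float:
    """Worst per-community ROC AUC for predicting membership from scores.

    For each community k, scorable nodes are classified as members of k
    (positives) vs not, ranked by score[., k]; the AUC is the midrank
    (Mann-Whitney) statistic, equivalent to sweeping the probability
    threshold over all distinct score values. Communities with no positive
    or no negative scorable node are skipped with a warning. Nodes whose
    order-o neighborhood is empty are excluded and reported as coverage.
    """
    z = densify_labels(z)
    k = int(z.max()) + 1
    if k < 2:
        raise ValidationError("min_community_auc requires K >= 2 communities")
    csm = neighbor_community_scores(g, z, o)
    mask = csm.scorable
    if csm.coverage < 1.0:
        logger.info(
            "min_community_auc: %d/%d nodes scorable at o=%d",
            int(mask.sum()),
            g.num_nodes,
            o,
        )
    aucs = []
    for comm in range(k):
        y = (z[mask] == comm).astype(int)
        if y.sum() == 0 or y.sum() == len(y):
            warnings.warn(
                f"community {comm}: no scorable positives and negatives; skipped",
                stacklevel=2,
            )
            continue
        aucs.append(float(roc_auc_score(y, csm.scores[mask, comm])))
    if not aucs:
        raise ValidationError("no community had both scorable positives and negatives")
    return min(aucs)


def _compress_detect_lift(g, num_supernodes, o_max, detector, gamma, seed):
    seeds = corehd_seeds(g, num_supernodes)
    assign = grow_supernodes(g, seeds, o_max=o_max)
    supernet = build_supernode_network(g, assign)
    z_w = detector(supernet.graph, gamma, seed)
    return assign, supernet, lift_partition(assign, z_w)


def quality_curve(
    g: Graph,
    s_values,
    replicates: int = 5,
    detector="louvain",
    o_max: int = 6,
    gamma: float = 1.0,
    rng_seed: int = 0,
    truth=None,
) -> pd.DataFrame:
    """NMI(z_full, z_sn) and U across a grid of super-node counts S.

    For each S and replicate: CoreHD seeds (deterministic, shared across
    replicates), grow, build W, detect on W, lift back, detect on the full
    graph with a fresh derived seed, then record NMI between the two
    partitions and the under-segmentation error of the super nodes against
    the full-graph partition. When planted ``truth`` labels are supplied,
    NMI(lifted, truth) is recorded too.
    """
    s_values = list(s_values)
    if not s_values:
        raise ValidationError("s_values must be non-empty")
    for s in s_values:
        if s >= g.num_nodes:
            raise ValidationError(f"S={s} must be < N={g.num_nodes}")
    det = get_detector(detector)
    tag = detector if isinstance(detector, str) else getattr(detector, "__name__", "custom")
    records = []
    for si, s in enumerate(s_values):
        for rep in range(replicates):
            seed_w = derive_seed(rng_seed, si, rep, 0)
            seed_full = derive_seed(rng_seed, si, rep, 1)
            assign, _, z_sn = _compress_detect_lift(g, s, o_max, det, gamma, seed_w)
            z_full = det(g, gamma, seed_full)
            row = {
                "S": s,
                "replicate": rep,
                "method": tag,
                "seed": seed_w,
            }
            measures = {
                "nmi_full_vs_sn": nmi(z_full, z_sn),
                "under_segmentation_error": under_segmentation_error(assign, z_full),
                "coverage": assign.coverage(),
            }
            if truth is not None:
                measures["nmi_sn_vs_truth"] = nmi(z_sn, truth)
                measures["nmi_full_vs_truth"] = nmi(z_full, truth)
            for name, value in measures.items():
                records.append(dict(row, metric=name, value=float(value)))
    return pd.DataFrame.from_records(records)


def variability_matrix(
    g: Graph,
    representation: str = "full",
    detectors=("louvain",),
    runs: int = 10,
    rng_seed: int = 0,
    num_supernodes: int | None = None,
    o_max: int = 6,
    gamma: float = 1.0,
) -> pd.DataFrame:
    """Pairwise NMI between repeated detector runs on one representation.

    ``representation`` is ``"full"`` (detect on g directly) or
    ``"supernode"`` (compress once with ``num_supernodes`` CoreHD seeds,
    detect on W per run, lift back). Records cover within-detector pairs and
    cross-detector pairs, the three comparison types of a variability panel.
    """
    if runs < 2:
        raise ValidationError("runs must be >= 2")
    if representation not in ("full", "supernode"):
        raise ValidationError("representation must be 'full' or 'supernode'")
    detectors = list(detectors)
    tags = [
        d if isinstance(d, str) else getattr(d, "__name__", f"custom{i}")
        for i, d in enumerate(detectors)
    ]
    if representation == "supernode":
        if num_supernodes is None:
            raise ValidationError("supernode representation requires num_supernodes")
        seeds = corehd_seeds(g, num_supernodes)
        assign = grow_supernodes(g, seeds, o_max=o_max)
        supernet = build_supernode_network(g, assign)

    partitions: dict[tuple[str, int], np.ndarray] = {}
    run_seeds: dict[tuple[str, int], int] = {}
    for di, d in enumerate(detectors):
        det = get_detector(d)
        for r in range(runs):
            seed = derive_seed(rng_seed, di, r)
            if representation == "full":
                z = det(g, gamma, seed)
            else:
                z = lift_partition(assign, det(supernet.graph, gamma, seed))
            partitions[(tags[di], r)] = z
            run_seeds[(tags[di], r)] = seed

    records = []
    keys = list(partitions)
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            (tag_a, run_a), (tag_b, run_b) = keys[a], keys[b]
            comparison = (
                f"within:{tag_a}" if tag_a == tag_b else f"between:{tag_a}|{tag_b}"
            )
            records.append(
                {
                    "representation": representation,
                    "detector_a": tag_a,
                    "run_a": run_a,
                    "seed_a": run_seeds[keys[a]],
                    "detector_b": tag_b,
                    "run_b": run_b,
                    "seed_b": run_seeds[keys[b]],
                    "comparison": comparison,
                    "metric": "pairwise_nmi",
                    "value": float(nmi(partitions[keys[a]], partitions[keys[b]])),
                }
            )
    return pd.DataFrame.from_records(records)


def summarize(result: pd.DataFrame, by=("metric",)) -> pd.DataFrame:
    """Mean and sd of ``value`` grouped by the given record columns."""
    by = [c for c in by if c in result.columns]
    g = result.groupby(by)["value"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out
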
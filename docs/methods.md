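# Methods

## Model and procedure

`supernodes` is a network pre-processing step for community detection. The
working assumption is the usual assortative one: communities are groups with
a greater weight of within-group edges than between-group edges, identified
either by maximizing modularity

Q = (1/2M′) Σᵢⱼ [aᵢⱼ − γ dᵢdⱼ/(2M′)] δ(zᵢ, zⱼ),

where dᵢ is node strength, M′ total edge weight and γ the resolution
parameter, or by maximizing the Bernoulli stochastic-block-model likelihood
with block-pair connection probabilities π. The package's contribution is
not a new detector but a compression of the input: if super nodes rarely
straddle community boundaries, detecting on the S-node weighted network
**W** is much cheaper and less run-to-run variable than detecting on all N
nodes, while lifting labels back yields nearly the same partition.

The pipeline is seeds → growth → **W** → detect → lift:

* **CoreHD seeding** repeatedly removes the highest-degree node of the
  current 2-core. Degree is measured inside the induced 2-core subgraph
  (CoreHD is a decycling procedure *on the core*, so core degrees are the
  relevant quantity). The 2-core here is the standard, possibly
  disconnected, maximal subgraph of minimum degree 2 obtained by iterated
  pruning — CoreHD only needs degrees within it, and the standard definition
  matches the dismantling literature the method comes from. When the 2-core
  empties before S seeds exist (forests, very sparse residual graphs) the
  selection continues as sequential highest-degree removal on the residual
  graph, so S seeds always exist and the procedure degenerates gracefully on
  trees. All ties break to the lowest node id; seeding is fully
  deterministic.
* **Growth** is synchronous: every round, each unassigned node with at least
  one assigned neighbor joins a super node, judged against the start-of-round
  assignment so the outcome is independent of iteration order. A contested
  node joins the super node with the greatest total connecting edge weight;
  remaining ties go to the earliest-selected seed. Both rules use only
  network information and keep growth deterministic. Nodes unassigned after
  `o_max` rounds form one shared periphery community; components containing
  no seed necessarily end there (logged as a warning).
* **W** aggregates crossing edge weights between distinct super nodes,
  drops within-super-node edges (no self loops) and ignores periphery
  nodes. Summed unit weights make W's weights edge counts. Conservation
  holds exactly: W's total weight + dropped within-super-node weight +
  periphery-touching weight = the original total.
* **Lift-back** gives every node its super node's community label; all
  periphery nodes share one fresh label. For under-segmentation error the
  periphery likewise participates as one extra super node by default (the
  choice is exposed as a flag; excluding it leaves periphery nodes out of
  every super node while still counting toward community sizes).

## Detection backends

`detect_modularity` is the modularity-maximizing detector contract: a
seeded Louvain-style agglomerative heuristic (local moving + aggregation)
honoring edge weights and γ. It is backed by networkx's Louvain
implementation plus two contract guarantees layered on top: the returned
partition is never worse in Q than the all-in-one or all-singletons
partitions, and identical (graph, γ, seed) always return the identical
label vector. Distinct seeds shuffle the node-processing order, reproducing
the run-to-run variability that repeated-run experiments measure.

Full agglomerative SBM samplers are prior art and stay behind the pluggable
detector registry. The built-in `"sbm"` entry is a clearly-labelled
surrogate: it detects with the modularity heuristic and then fits and scores
the Bernoulli block matrix of the result. Raw maximum likelihood cannot
choose K (it always improves under refinement), so the scale comes from the
modularity step while the block-model code supplies π̂ and the
log-likelihood. The likelihood is evaluated once per unordered node pair —
the ordered-pair form seen in textbook notation is exactly twice this value
for symmetric π and has the same argmax. Hard probabilities (π entries of
exactly 0 or 1) contribute nothing over pairs they predict perfectly and
−∞ if contradicted.

## Comparing partitions across scales

Partitions of the full network and of a compressed representation live at
different scales, so three matched comparisons are provided:

* **NMI** from the contingency table, normalized by the arithmetic mean of
  the two label entropies. Natural logarithms are used (the value is
  base-invariant; fixing the base makes intermediate quantities
  bit-reproducible). Degenerate cases: two single-community partitions are
  identical, so NMI = 1 by convention; one trivial vs one non-trivial
  yields 0 naturally.
* **Matched resolution**: nodes are ranked by the size of their containing
  community (ascending; all members of a community — and of equal-size
  communities — share a rank), and the full-network γ grid (default 25
  log-spaced points in [0.05, 2.5], 5 detector runs per γ) is scored by
  Kendall's τ-b against the reference ranking. τ-b is the variant of choice
  because these rankings are massively tied; a fully tied ranking (every
  community the same size) makes τ undefined and is treated as 0 with a
  warning — on *exactly balanced* synthetic fixtures the matching is
  therefore uninformative, which real networks' skewed community sizes
  avoid. Ties in the grid resolve to the smaller γ.
* **Matched block count** simply hands K of the reference partition to
  fixed-K backends.

The permutation baseline shuffles which node carries which label (preserving
community sizes, 1000 permutations by default) and reports mean ± sd NMI —
the chance-agreement floor against which observed NMI is judged.

## Local-agreement prediction task

For a partition z and neighborhood order o, node i's score for community k
is the fraction of nodes within distance ≤ o of i (cumulative neighborhoods;
i excluded) labelled k. Each community defines a binary classification of
the scorable nodes; sweeping the probability threshold over all distinct
scores traces the ROC, and the AUC is computed by the midrank
(Mann-Whitney) statistic — equivalent to trapezoidal integration with ties
counted half. The summary statistic is the minimum AUC over communities.
Nodes with an empty order-o neighborhood are excluded from scoring rather
than scored zero (scoring them would manufacture artificial negatives);
their fraction is reported as coverage. Communities with no scorable
positive or no scorable negative are skipped with a warning.

## Synthetic study conditions

Two seeded generators stand in for real network data:

* `planted_partition_graph(n, K, p_in, p_out, seed)` — K near-equal blocks
  (the first n mod K blocks get one extra node, so truth partitions are
  reproducible from (n, K) alone); within-block pairs connect with p_in,
  cross-block with p_out, independently. The standing study conditions are
  n = 2000, K = 4, p_in = 0.05, p_out = 0.002: mean within-degree ≈ 25
  against cross-degree ≈ 3, a strongly assortative regime where full-network
  Louvain recovers the planted blocks essentially perfectly, isolating
  compression quality as the quantity under study.
* `ring_of_cliques(k, c)` — k c-cliques joined in a ring by single bridge
  edges between the lowest-id node of each clique; unambiguous communities
  with exactly k·c(c−1)/2 + k edges.

What these conditions do *not* emulate: heavy-tailed degree distributions,
community size heterogeneity, overlapping or hierarchical structure, and
the 10⁴–10⁵-node scale of real web/social graphs. Passing tests demonstrate
correctness of the machinery and the qualitative behaviors (NMI rises and U
falls with S; compressed detection is at least as stable run-to-run as full
detection; permutation NMI ≈ 0) at desk scale — not the headline numbers
any particular real network would produce.

Experiment sizes in the test-suite mirrors (S grids of 10–80 over n = 2000,
5 replicates, 10-run variability panels) were chosen as the smallest
problems that still exhibit those trends clearly.

One intrinsic behavior worth knowing: with multiple seeds per true
community, a node's within-community edge weight fragments across same-
community super nodes while its few cross-community edges can concentrate on
one foreign super node, and nodes whose only seed-adjacent neighbors are
foreign are claimed by them in the first growth round. Super nodes therefore
straddle boundaries at a low but non-zero rate even in strongly assortative
graphs — exactly what under-segmentation error measures — and lifted-partition
NMI saturates below 1 at small S.

## Numerical and design choices

* Node ids are dense integers 0..N−1 internally (original labels kept in a
  side map; all CLI artifacts are written keyed by original labels so files
  from different commands stay mutually consistent). The dense total order
  makes every tie-break deterministic and testable.
* Modularity is evaluated community-wise in O(M); with all-unit weights the
  all-in-one partition at γ = 1 evaluates to exactly 0.0 in floating point.
  Total edge weight M′ replaces edge count for weighted graphs — required
  for W, whose weights are counts.
* Every stochastic stage receives a child seed derived from one master seed
  via `numpy` SeedSequence spawn keys (kept < 2³¹), recorded in every output
  record; a single integer reproduces an entire experiment.
* Bare edge lists cannot represent isolated nodes; the writer warns. File
  round-trips are exact on the labelled edge set.
* Validation errors exit the CLI with code 2, runtime errors with 3;
  pipeline errors name the failing stage.

## Known limitations

* The Bernoulli SBM scoring applies to unweighted graphs only (weighted
  input raises); no degree-corrected or nested variants.
* Undirected simple graphs only — no directed, signed, attributed or
  bipartite support, no streaming.
* Matched-resolution selection is uninformative when all communities have
  equal sizes (see above).
* Very small compressed networks are degenerate for modularity: a two-super-
  node W with one edge always merges (any split has Q = −γ/2 < 0), since
  within-super-node cohesion is deliberately dropped with the self loops.
  Compression is meant for S large enough that W retains structure.
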
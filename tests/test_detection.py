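import numpy as np
import pytest

from supernodes import (
    Graph,
    ValidationError,
    detect_modularity,
    estimate_block_matrix,
    matched_block_count,
    matched_resolution,
    modularity_score,
    nmi,
    planted_partition_graph,
    sbm_log_likelihood,
)
from supernodes.detection import BlockMatrix, community_size_ranks, get_detector

from oracles import (
    brute_force_best_modularity,
    brute_force_sbm_loglik,
    random_er_edges,
)


class TestModularityScore:
    def test_all_in_one_is_exactly_zero(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 30))
            g = Graph(n, random_er_edges(n, 0.3, rng))
            if g.num_edges == 0:
                continue
            assert modularity_score(g, np.zeros(n, dtype=int), 1.0) == 0.0

    def test_triangle_singletons(self):
        g = Graph(3, [(0, 1), (0, 2), (1, 2)])
        assert modularity_score(g, [0, 1, 2], 1.0) == pytest.approx(-1 / 3)

    def test_two_disjoint_triangles_components(self, disjoint_triangles):
        assert modularity_score(disjoint_triangles, [0, 0, 0, 1, 1, 1], 1.0) == 0.5

    def test_relabel_invariance(self, rng, disjoint_triangles):
        z = np.array([0, 0, 0, 1, 1, 1])
        for perm in ([1, 0], [5, 3]):
            relabeled = np.array(perm)[z]
            assert modularity_score(disjoint_triangles, relabeled, 1.3) == (
                pytest.approx(modularity_score(disjoint_triangles, z, 1.3))
            )

    def test_empty_graph_rejected(self):
        with pytest.raises(ValidationError):
            modularity_score(Graph(3), [0, 0, 0], 1.0)


class TestDetectModularity:
    def test_recovers_components_of_disjoint_triangles(self, disjoint_triangles):
        z = detect_modularity(disjoint_triangles, 1.0, rng_seed=4)
        q = modularity_score(disjoint_triangles, z, 1.0)
        best_q, _ = brute_force_best_modularity(6, disjoint_triangles.edges())
        assert q == pytest.approx(best_q)  # the unique optimum Q = 0.5
        assert nmi(z, [0, 0, 0, 1, 1, 1]) == 1.0

    def test_complete_graph_is_one_community(self):
        k4 = Graph(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
        z = detect_modularity(k4, 1.0, rng_seed=0)
        assert len(np.unique(z)) == 1
        best_q, parts = brute_force_best_modularity(4, k4.edges())
        assert len(parts) == 1  # exhaustive oracle agrees: any split has Q < 0

    def test_deterministic_per_seed(self, small_planted):
        g = small_planted.graph
        a = detect_modularity(g, 1.0, rng_seed=77)
        b = detect_modularity(g, 1.0, rng_seed=77)
        assert a.tolist() == b.tolist()

    def test_never_worse_than_trivial_partitions(self, rng):
        for gamma in (0.3, 1.0, 2.0):
            n = 20
            g = Graph(n, random_er_edges(n, 0.2, rng))
            z = detect_modularity(g, gamma, rng_seed=1)
            q = modularity_score(g, z, gamma)
            assert q >= modularity_score(g, np.zeros(n, dtype=int), gamma) - 1e-12
            assert q >= modularity_score(g, np.arange(n), gamma) - 1e-12


class TestBlockMatrix:
    def test_mle_on_disjoint_triangles(self, disjoint_triangles):
        bm = estimate_block_matrix(disjoint_triangles, [0, 0, 0, 1, 1, 1])
        assert bm.pi.tolist() == [[1.0, 0.0], [0.0, 1.0]]

    def test_single_block_triangle(self):
        g = Graph(3, [(0, 1), (0, 2), (1, 2)])
        assert estimate_block_matrix(g, [0, 0, 0]).pi.tolist() == [[1.0]]

    def test_singleton_block_zero_pairs_convention(self):
        assert estimate_block_matrix(Graph(1), [0]).pi.tolist() == [[0.0]]

    def test_weighted_graph_rejected(self):
        g = Graph(2, [(0, 1, 2.0)])
        with pytest.raises(ValidationError):
            estimate_block_matrix(g, [0, 0])


class TestSbmLogLikelihood:
    def test_perfect_fit_is_zero(self, disjoint_triangles):
        z = [0, 0, 0, 1, 1, 1]
        bm = estimate_block_matrix(disjoint_triangles, z)
        assert sbm_log_likelihood(disjoint_triangles, z, bm) == 0.0

    def test_single_pair_closed_form(self):
        g = Graph(2, [(0, 1)])
        ll = sbm_log_likelihood(g, [0, 0], BlockMatrix([[0.5]]))
        assert ll == pytest.approx(np.log(0.5))

    def test_empty_graph_probability_zero_fits_perfectly(self):
        assert sbm_log_likelihood(Graph(3), [0, 0, 0], BlockMatrix([[0.0]])) == 0.0

    def test_contradicted_hard_probability_is_minus_inf(self):
        g = Graph(2, [(0, 1)])
        assert sbm_log_likelihood(g, [0, 0], BlockMatrix([[0.0]])) == float("-inf")

    def test_matches_brute_force_pair_product(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 8))
            edges = random_er_edges(n, 0.4, rng)
            g = Graph(n, edges)
            z = rng.integers(0, min(3, n), size=n)
            z[0] = 0  # keep labels dense enough after densification
            zd = np.unique(z, return_inverse=True)[1]
            k = zd.max() + 1
            pi = rng.uniform(0.05, 0.95, size=(k, k))
            pi = (pi + pi.T) / 2
            ll = sbm_log_likelihood(g, zd, BlockMatrix(pi))
            assert ll == pytest.approx(
                brute_force_sbm_loglik(n, edges, zd, pi), abs=1e-10
            )

    def test_mle_beats_perturbed_matrices(self, rng):
        n = 12
        g = Graph(n, random_er_edges(n, 0.35, rng))
        z = np.array([0] * 6 + [1] * 6)
        bm = estimate_block_matrix(g, z)
        ll_star = sbm_log_likelihood(g, z, bm)
        for _ in range(20):
            pert = np.clip(bm.pi + rng.uniform(-0.2, 0.2, bm.pi.shape), 0.01, 0.99)
            pert = (pert + pert.T) / 2
            assert ll_star >= sbm_log_likelihood(g, z, BlockMatrix(pert)) - 1e-12


class TestMatchedScale:
    def test_block_count(self):
        assert matched_block_count([0, 0, 1, 1]) == 2
        assert matched_block_count([7, 7, 7]) == 1
        assert matched_block_count([0, 1, 2, 1]) == 3

    def test_identical_reference_selects_tau_one(self, small_planted):
        g, truth = small_planted.graph, small_planted.truth
        gamma_star, curve = matched_resolution(
            g, truth, gammas=[0.8, 1.0], runs_per_gamma=2, rng_seed=0
        )
        taus = dict(curve)
        assert max(taus.values()) == pytest.approx(1.0)
        assert taus[gamma_star] == max(taus.values())

    def test_degenerate_all_tied_warns_and_returns_zero(self):
        g = Graph(3, [(0, 1), (0, 2), (1, 2)])
        with pytest.warns(UserWarning, match="tau undefined"):
            gamma_star, curve = matched_resolution(
                g, [0, 0, 0], gammas=[0.1], runs_per_gamma=1, rng_seed=0
            )
        assert curve == [(0.1, 0.0)]

    def test_recovers_resolution_matching_planted_blocks(self, small_planted):
        g, truth = small_planted.graph, small_planted.truth
        gamma_star, _ = matched_resolution(
            g, truth, gammas=[0.25, 1.0, 2.5], runs_per_gamma=2, rng_seed=3
        )
        z = detect_modularity(g, gamma_star, rng_seed=9)
        assert nmi(z, truth) >= 0.9

    def test_size_ranks_share_rank_within_and_across_equal_communities(self):
        ranks = community_size_ranks([0, 0, 1, 1, 2, 2, 2])
        assert ranks.tolist() == [2, 2, 2, 2, 3, 3, 3]


def test_detector_registry_rejects_unknown_tag():
    with pytest.raises(ValidationError):
        get_detector("nope")


def test_sbm_surrogate_detector_runs(self=None):
    bundle = planted_partition_graph(120, 3, 0.3, 0.02, rng_seed=2)
    z = get_detector("sbm")(bundle.graph, 1.0, 5)
    assert nmi(z, bundle.truth) >= 0.9
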
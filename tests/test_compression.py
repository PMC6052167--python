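import numpy as np
import pytest

from supernodes import (
    PERIPHERY,
    Graph,
    ValidationError,
    build_supernode_network,
    corehd_seeds,
    grow_supernodes,
    lift_partition,
)
from supernodes.compression import read_assignment, write_assignment

from oracles import random_er_edges


class TestGrowth:
    def test_one_round_engulfs_both_triangles(self, two_triangles):
        a = grow_supernodes(two_triangles, [2, 3], o_max=6)
        assert a.assignment.tolist() == [0, 0, 0, 1, 1, 1]
        assert a.coverage() == 1.0

    def test_equal_weight_tie_goes_to_lower_seed_rank(self):
        g = Graph(3, [(0, 1), (1, 2)])
        a = grow_supernodes(g, [0, 2], o_max=6)
        assert a.assignment.tolist() == [0, 0, 1]
        # reversing the seed order flips the tie
        b = grow_supernodes(g, [2, 0], o_max=6)
        assert b.assignment.tolist() == [1, 0, 0]

    def test_o_max_limits_growth_to_periphery(self, path5):
        a = grow_supernodes(path5, [2], o_max=1)
        assert a.assignment.tolist() == [PERIPHERY, 0, 0, 0, PERIPHERY]
        assert set(a.periphery_nodes()) == {0, 4}

    def test_weight_beats_rank(self):
        # node 2 has weight 2 to seed 1's super node, weight 1 to seed 0's
        g = Graph(4, [(0, 2, 1.0), (1, 2, 2.0), (1, 3, 1.0)])
        a = grow_supernodes(g, [0, 1], o_max=1)
        assert a.assignment.tolist() == [0, 1, 1, 1]

    def test_claims_use_start_of_round_state(self):
        # node 3 is 2 hops from seed 0 and 1 hop from nothing in round 1,
        # so it joins in round 2 regardless of iteration order
        g = Graph(4, [(0, 1), (1, 3), (2, 3)])
        a = grow_supernodes(g, [0, 2], o_max=6)
        assert a.assignment.tolist() == [0, 0, 1, 1]

    def test_empty_seed_set_rejected(self, path5):
        with pytest.raises(ValidationError):
            grow_supernodes(path5, [], o_max=6)

    def test_monotone_coverage_in_o_max(self, rng):
        n = 60
        g = Graph(n, random_er_edges(n, 0.06, rng))
        seeds = corehd_seeds(g, 4)
        prev = -1.0
        for o_max in (1, 2, 3, 6):
            cov = grow_supernodes(g, seeds, o_max=o_max).coverage()
            assert cov >= prev
            prev = cov

    def test_full_coverage_at_diameter_with_seed_per_component(self):
        g = Graph(6, [(0, 1), (1, 2), (3, 4), (4, 5)])
        a = grow_supernodes(g, [0, 4], o_max=2)
        assert len(a.periphery_nodes()) == 0


class TestSuperNodeNetwork:
    def test_bridge_weight_between_triangles(self, two_triangles):
        a = grow_supernodes(two_triangles, [2, 3], o_max=6)
        net = build_supernode_network(two_triangles, a)
        assert net.graph.edges() == [(0, 1, 1.0)]
        assert net.membership == [{0, 1, 2}, {3, 4, 5}]

    def test_single_supernode_has_no_edges(self, two_triangles):
        a = grow_supernodes(two_triangles, [2], o_max=6)
        net = build_supernode_network(two_triangles, a)
        assert net.graph.num_nodes == 1
        assert net.graph.num_edges == 0

    def test_path_split_crossing_weight(self):
        g = Graph(4, [(0, 1), (1, 2), (2, 3)])
        a = grow_supernodes(g, [0, 3], o_max=6)
        net = build_supernode_network(g, a)
        assert net.graph.edges() == [(0, 1, 1.0)]

    def test_conservation_identity(self, rng):
        for _ in range(15):
            n = int(rng.integers(8, 50))
            g = Graph(n, random_er_edges(n, 0.12, rng))
            if g.num_edges == 0:
                continue
            s = int(rng.integers(1, 5))
            seeds = corehd_seeds(g, s)
            o_max = int(rng.integers(1, 4))
            a = grow_supernodes(g, seeds, o_max=o_max)
            net = build_supernode_network(g, a)
            assign = a.assignment
            dropped_within = sum(
                w
                for u, v, w in g.edges()
                if assign[u] == assign[v] and assign[u] != PERIPHERY
            )
            periph_touch = sum(
                w
                for u, v, w in g.edges()
                if assign[u] == PERIPHERY or assign[v] == PERIPHERY
            )
            assert net.graph.total_weight + dropped_within + periph_touch == (
                pytest.approx(g.total_weight)
            )
            # membership sets + periphery partition all nodes
            seen = set()
            for m in net.membership:
                assert not (m & seen)
                seen |= m
            assert not (net.periphery & seen)
            assert seen | net.periphery == set(range(n))

    def test_every_node_a_seed_is_identity(self, two_triangles):
        g = two_triangles
        a = grow_supernodes(g, list(range(g.num_nodes)), o_max=6)
        net = build_supernode_network(g, a)
        assert net.graph == g
        z = np.array([0, 0, 1, 1, 2, 2])
        assert lift_partition(a, z).tolist() == z.tolist()


class TestLiftPartition:
    def test_direct_relabeling(self, two_triangles):
        a = grow_supernodes(two_triangles, [2, 3], o_max=6)
        assert lift_partition(a, [0, 1]).tolist() == [0, 0, 0, 1, 1, 1]

    def test_constant_partition(self, two_triangles):
        a = grow_supernodes(two_triangles, [2, 3], o_max=6)
        assert lift_partition(a, [0, 0]).tolist() == [0] * 6

    def test_periphery_gets_shared_fresh_label(self, path5):
        a = grow_supernodes(path5, [2], o_max=1)
        z = lift_partition(a, [0])
        assert z[1] == z[2] == z[3] == 0
        assert z[0] == z[4] == 1  # fresh label distinct from super-node labels

    def test_length_mismatch_rejected(self, path5):
        a = grow_supernodes(path5, [2], o_max=1)
        with pytest.raises(ValidationError):
            lift_partition(a, [0, 1])


def test_assignment_file_roundtrip(tmp_path, path5):
    a = grow_supernodes(path5, [2], o_max=1)
    path = tmp_path / "assignment.tsv"
    write_assignment(a, path)
    b = read_assignment(path, o_max=1)
    assert b.assignment.tolist() == a.assignment.tolist()
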
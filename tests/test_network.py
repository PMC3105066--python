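"""Network generators, radius-2 expansion and topology statistics."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from metanorms import (
    InteractionNetwork,
    NetworkStats,
    generate_ba,
    generate_er,
    generate_watts,
    network_stats,
    node_clustering,
    node_triplets,
    radius2_closure,
    sample_networks,
)


def complete(n):
    return InteractionNetwork(n, itertools.combinations(range(n), 2))


class TestInteractionNetwork:
    def test_rejects_self_loops_and_bad_indices(self):
        with pytest.raises(ValueError, match="self-loop"):
            InteractionNetwork(3, [(1, 1)])
        with pytest.raises(ValueError, match="outside"):
            InteractionNetwork(3, [(0, 3)])
        with pytest.raises(ValueError):
            InteractionNetwork(0, [])

    def test_duplicate_edges_collapse_and_symmetry(self):
        net = InteractionNetwork(3, [(0, 1), (1, 0), (0, 1)])
        assert net.n_edges == 1
        assert 1 in net.neighbors(0) and 0 in net.neighbors(1)

    def test_degree_sum_is_twice_edges(self):
        net = generate_er(30, 0.2, seed=5)
        assert net.degrees().sum() == 2 * net.n_edges


class TestGenerators:
    def test_ba_m1_is_triangle_free_tree(self):
        net = generate_ba(50, 1, seed=0)
        assert net.n_edges == 49
        assert network_stats(net).interconnectedness == 0.0
        assert nx.is_connected(net.to_networkx())

    def test_ba_minimal_case_is_complete_triangle(self):
        net = generate_ba(3, 2, seed=0)
        assert net == complete(3)

    def test_ba_edge_count_deterministic_and_mean_degree(self):
        # complete seed on m nodes, then m attachments per new node
        nets = [generate_ba(50, 2, seed=s) for s in range(100)]
        for net in nets:
            assert net.n_edges == math.comb(2, 2) + (50 - 2) * 2
        mean_degree = np.mean([net.degrees().mean() for net in nets])
        assert mean_degree == pytest.approx(2 * 2 * (1 - 2 / 50), abs=0.1)

    def test_ba_parameter_validation(self):
        with pytest.raises(ValueError):
            generate_ba(3, 0)
        with pytest.raises(ValueError):
            generate_ba(2, 2)

    def test_watts_lattice_clustering_is_half_at_k4(self, ring50):
        # on the k=4 ring, 3 of the 6 neighbour pairs are linked
        assert ring50.n_edges == 50 * 4 // 2
        for i in range(50):
            assert node_clustering(ring50, i) == pytest.approx(0.5)

    def test_watts_k2_cycle_is_triangle_free(self):
        net = generate_watts(50, 2, 0.0, seed=0)
        assert network_stats(net).interconnectedness == 0.0

    def test_watts_full_rewiring_loses_lattice_clustering(self):
        # beta=1 should look like a random graph of equal density
        cs = []
        for s in range(60):
            stats = network_stats(generate_watts(50, 4, 1.0, seed=s))
            cs.append(stats.mean_clustering)
        assert np.mean(cs) == pytest.approx(4 / 49, abs=0.04)

    def test_watts_parameter_validation(self):
        with pytest.raises(ValueError):
            generate_watts(50, 3, 0.1)
        with pytest.raises(ValueError):
            generate_watts(50, 4, 1.5)
        with pytest.raises(ValueError):
            generate_watts(4, 4, 0.0)

    def test_er_extremes(self):
        full = generate_er(50, 1.0, seed=0)
        assert full == complete(50)
        assert node_triplets(full, 0) == math.comb(49, 2) == 1176
        empty = generate_er(50, 0.0, seed=0)
        assert empty.n_edges == 0

    def test_er_mean_edge_count(self):
        counts = [generate_er(50, 0.1, seed=s).n_edges for s in range(200)]
        # expected 0.1 * C(50,2) = 122.5, sd of the mean ~ 0.74
        assert np.mean(counts) == pytest.approx(122.5, abs=3.0)

    def test_er_parameter_validation(self):
        with pytest.raises(ValueError):
            generate_er(10, 1.2)

    @pytest.mark.parametrize(
        "gen,kwargs",
        [
            (generate_ba, {"n": 40, "m": 2}),
            (generate_watts, {"n": 40, "k": 4, "beta": 0.3}),
            (generate_er, {"n": 40, "p": 0.1}),
        ],
    )
    def test_generators_are_seed_reproducible(self, gen, kwargs):
        assert gen(**kwargs, seed=99) == gen(**kwargs, seed=99)


class TestRadius2:
    def test_cycle5_closes_to_complete(self):
        c5 = InteractionNetwork(5, [(i, (i + 1) % 5) for i in range(5)])
        assert radius2_closure(c5) == complete(5)

    def test_star_closes_to_complete(self):
        star = InteractionNetwork(7, [(0, i) for i in range(1, 7)])
        assert radius2_closure(star) == complete(7)

    def test_path4_gains_only_distance2_links(self):
        p4 = InteractionNetwork(4, [(0, 1), (1, 2), (2, 3)])
        closed = radius2_closure(p4)
        assert closed.edges == frozenset(
            {(0, 1), (0, 2), (1, 2), (1, 3), (2, 3)}
        )  # the distance-3 pair (0, 3) stays unlinked

    def test_fixed_points_are_unions_of_cliques(self):
        # complete components have no distance-2 pairs left to add
        assert radius2_closure(complete(8)) == complete(8)
        two_cliques = InteractionNetwork(
            6, list(itertools.combinations(range(3), 2))
            + [(i + 3, j + 3) for i, j in itertools.combinations(range(3), 2)]
        )
        assert radius2_closure(two_cliques) == two_cliques

    def test_iterated_closure_reaches_a_fixed_point(self):
        net = generate_er(30, 0.1, seed=4)
        cur = net
        for _ in range(6):
            nxt = radius2_closure(cur)
            assert nxt.edges >= cur.edges  # closure only adds links
            if nxt == cur:
                break
            cur = nxt
        assert radius2_closure(cur) == cur

    def test_matches_bfs_oracle(self):
        net = generate_er(25, 0.12, seed=8)
        closed = radius2_closure(net)
        dist = dict(nx.all_pairs_shortest_path_length(net.to_networkx(), cutoff=2))
        expected = {
            (min(i, j), max(i, j))
            for i, d in dist.items()
            for j, length in d.items()
            if i != j and length <= 2
        }
        assert closed.edges == frozenset(expected)


class TestStatistics:
    def test_node_triplets_on_named_graphs(self):
        k4 = complete(4)
        assert all(node_triplets(k4, i) == 3 for i in range(4))
        star = InteractionNetwork(6, [(0, i) for i in range(1, 6)])
        assert node_triplets(star, 0) == 0
        with pytest.raises(IndexError):
            node_triplets(k4, 4)

    def test_node_triplets_matches_exhaustive_enumeration(self):
        net = generate_er(10, 0.4, seed=3)
        for i in range(10):
            brute = sum(
                1
                for j, l in itertools.combinations(range(10), 2)
                if j in net.neighbors(i)
                and l in net.neighbors(i)
                and l in net.neighbors(j)
            )
            assert node_triplets(net, i) == brute

    def test_node_triplets_matches_networkx_triangles(self):
        net = generate_er(30, 0.2, seed=6)
        tri = nx.triangles(net.to_networkx())
        for i in range(30):
            assert node_triplets(net, i) == tri[i]

    def test_node_clustering_definition(self):
        assert node_clustering(complete(4), 0) == 1.0
        star = InteractionNetwork(6, [(0, i) for i in range(1, 6)])
        assert node_clustering(star, 0) == 0.0
        with pytest.raises(ValueError, match="degree"):
            node_clustering(star, 1)

    def test_stats_on_complete_graph(self):
        stats = network_stats(complete(50))
        assert stats.avg_degree == 49.0
        assert stats.interconnectedness == 1176.0
        assert stats.clustering_by_degree[49] == 1.0
        assert stats.degree_dist == {49: 1.0}

    def test_stats_on_tree(self):
        stats = network_stats(generate_ba(40, 1, seed=2))
        assert stats.interconnectedness == 0.0

    def test_interconnectedness_is_three_triangles_per_node(self):
        net = generate_er(30, 0.25, seed=9)
        n_triangles = sum(nx.triangles(net.to_networkx()).values()) / 3
        stats = network_stats(net)
        assert stats.interconnectedness == pytest.approx(3 * n_triangles / 30)

    def test_degree_distribution_sums_to_one(self):
        stats = network_stats(generate_er(40, 0.15, seed=1))
        assert sum(stats.degree_dist.values()) == pytest.approx(1.0)

    def test_homogeneous_stats_constructor_roundtrip(self):
        stats = NetworkStats.homogeneous(4.0, 3.0, n=50)
        assert stats.avg_degree == 4.0
        assert stats.interconnectedness == 3.0
        assert stats.clustering_by_degree[4] == pytest.approx(0.5)


class TestEnsemble:
    def test_sample_networks_reproducible_and_radius(self):
        specs = [
            {"model": "watts", "n": 30, "k": 4, "beta": 0.2},
            {"model": "ba", "n": 30, "m": 2, "radius": 2},
        ]
        a = sample_networks(specs, samples_per_spec=2, seed=5)
        b = sample_networks(specs, samples_per_spec=2, seed=5)
        assert len(a) == 4
        assert all(x[1] == y[1] for x, y in zip(a, b))
        assert a[2][0]["radius"] == 2

    def test_sample_networks_rejects_unknown_model(self):
        with pytest.raises(ValueError, match="unknown network model"):
            sample_networks([{"model": "lattice", "n": 10}])


@given(
    model=st.sampled_from(["ba", "watts", "er"]),
    seed=st.integers(0, 10_000),
)
def test_generated_network_invariants(model, seed):
    """Every generated network satisfies the structural invariants."""
    if model == "ba":
        net = generate_ba(25, 2, seed=seed)
    elif model == "watts":
        net = generate_watts(25, 4, 0.3, seed=seed)
    else:
        net = generate_er(25, 0.15, seed=seed)
    degrees = net.degrees()
    assert degrees.sum() == 2 * net.n_edges
    for i in range(net.n):
        assert i not in net.neighbors(i)
        for j in net.neighbors(i):
            assert i in net.neighbors(j)
    stats = network_stats(net)
    n_triangles = sum(nx.triangles(net.to_networkx()).values()) / 3
    assert stats.interconnectedness == pytest.approx(3 * n_triangles / net.n)
    for k, c in stats.clustering_by_degree.items():
        assert 0.0 <= c <= 1.0
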
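"""Modularity score, simulated-annealing optimiser, oracle and node roles."""

import networkx as nx
import numpy as np
import pytest

from settlenet.io import DataError
from settlenet.modularity import (anneal_partition, brute_force_partition,
                                  cartographic_roles, modularity_score)


def _two_triangles():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                      ("x", "y"), ("y", "z"), ("x", "z")])
    return g


class TestScore:
    def test_single_module_is_zero(self):
        g = nx.gnp_random_graph(10, 0.5, seed=1)
        assert modularity_score(g, dict.fromkeys(g.nodes, 0)) == pytest.approx(0.0)

    def test_two_clique_components_give_half(self):
        g = _two_triangles()
        part = {v: (0 if v in "abc" else 1) for v in g.nodes}
        assert modularity_score(g, part) == pytest.approx(0.5)

    def test_triangle_split_hand_value(self):
        g = nx.complete_graph(3)
        assert modularity_score(g, {0: 0, 1: 1, 2: 1}) == pytest.approx(-2 / 9)

    def test_matches_networkx_weighted_modularity(self):
        rng = np.random.default_rng(5)
        g = nx.gnp_random_graph(12, 0.4, seed=3)
        for u, v in g.edges():
            g[u][v]["weight"] = float(rng.uniform(0.2, 2.0))
        part = {v: v % 3 for v in g.nodes}
        communities = [{v for v in g.nodes if v % 3 == m} for m in range(3)]
        expected = nx.community.modularity(g, communities, weight="weight")
        assert modularity_score(g, part) == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_relabelling(self):
        g = _two_triangles()
        a = {v: (0 if v in "abc" else 1) for v in g.nodes}
        b = {v: (7 if v in "abc" else 3) for v in g.nodes}
        assert modularity_score(g, a) == modularity_score(g, b)

    def test_uncovered_node_rejected(self):
        g = nx.path_graph(3)
        with pytest.raises(DataError):
            modularity_score(g, {0: 0, 1: 0})


class TestBruteForce:
    def test_triangle_optimum_is_single_module(self):
        part = brute_force_partition(nx.complete_graph(3))
        assert part.n_modules == 1
        assert part.Q == pytest.approx(0.0)

    def test_two_triangles_optimum_is_components(self):
        part = brute_force_partition(_two_triangles())
        assert part.Q == pytest.approx(0.5)
        assert part.n_modules == 2

    def test_single_edge_prefers_one_module(self):
        g = nx.Graph([("a", "b")])
        part = brute_force_partition(g)
        assert part.n_modules == 1
        assert part.Q == pytest.approx(0.0)  # the split scores -1/2

    def test_size_cap(self):
        with pytest.raises(DataError):
            brute_force_partition(nx.path_graph(13))


class TestAnneal:
    def test_recovers_two_triangle_components(self):
        part = anneal_partition(_two_triangles(), seed=0)
        assert part.Q == pytest.approx(0.5)
        mods = {part.assignment[v] for v in "abc"}
        assert len(mods) == 1
        assert part.assignment["x"] != part.assignment["a"]

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_matches_brute_force_on_small_graphs(self, seed):
        g = nx.gnp_random_graph(7, 0.4, seed=seed)
        bf = brute_force_partition(g)
        sa = anneal_partition(g, seed=seed, compute_roles=False)
        assert sa.Q == pytest.approx(bf.Q, abs=1e-9)

    def test_planted_blocks_recovered(self):
        from sklearn.metrics import adjusted_rand_score
        g = nx.planted_partition_graph(4, 10, 0.9, 0.05, seed=7)
        part = anneal_partition(g, cooling_factor=0.95, seed=1, compute_roles=False)
        truth = [v // 10 for v in sorted(g.nodes)]
        found = [part.assignment[v] for v in sorted(g.nodes)]
        assert adjusted_rand_score(truth, found) >= 0.9

    def test_never_worse_than_single_module(self):
        for seed in range(3):
            g = nx.gnp_random_graph(10, 0.3, seed=seed)
            g.remove_nodes_from(list(nx.isolates(g)))
            part = anneal_partition(g, seed=seed, compute_roles=False)
            assert part.Q >= -1e-12

    def test_same_seed_is_reproducible(self):
        g = nx.gnp_random_graph(15, 0.3, seed=11)
        a = anneal_partition(g, cooling_factor=0.9, seed=42)
        b = anneal_partition(g, cooling_factor=0.9, seed=42)
        assert a.assignment == b.assignment
        assert a.Q == b.Q

    def test_empty_network_rejected(self):
        with pytest.raises(DataError):
            anneal_partition(nx.Graph())


class TestRoles:
    def test_fully_intra_module_node_has_zero_participation(self):
        g = _two_triangles()
        part = anneal_partition(g, seed=0)
        assert np.allclose(part.roles["P"], 0.0)

    def test_equal_split_participation_is_half(self):
        g = nx.Graph([("hub", "a"), ("hub", "b")])
        from settlenet.modularity import ModulePartition
        part = ModulePartition({"hub": 0, "a": 0, "b": 1}, 0.0)
        roles = cartographic_roles(g, part)
        assert roles.loc["hub", "P"] == pytest.approx(0.5)

    def test_equal_within_strength_gives_zero_z(self):
        g = nx.complete_graph(4)
        from settlenet.modularity import ModulePartition
        part = ModulePartition(dict.fromkeys(g.nodes, 0), 0.0)
        roles = cartographic_roles(g, part)
        assert np.allclose(roles["z"], 0.0)

    def test_isolated_node_convention(self):
        g = nx.Graph()
        g.add_node("lonely")
        from settlenet.modularity import ModulePartition
        roles = cartographic_roles(g, ModulePartition({"lonely": 0}, 0.0))
        assert roles.loc["lonely", "z"] == 0.0
        assert roles.loc["lonely", "P"] == 0.0
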
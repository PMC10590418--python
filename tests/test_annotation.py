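"""Settlement overlays: fractions, purity, collapsed networks, bridging,
betweenness screening, exclusivity and rare families."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from settlenet.annotation import (betweenness_degree, bridging_nodes,
                                  collapse_modules, exclusive_taxa,
                                  label_module_purity,
                                  module_settlement_composition,
                                  node_settlement_fractions, nodes_of_interest,
                                  rare_taxa)
from settlenet.io import CountTable, TaxonomyTable, RANKS, UNASSIGNED
from settlenet.modularity import ModulePartition


@pytest.fixture()
def category_table():
    # 4 samples: 2 high, 1 medium, 1 low; equal depth 10
    df = pd.DataFrame({"h1": [3, 0, 2, 5], "h2": [3, 0, 2, 5],
                       "m1": [2, 0, 3, 5], "l1": [0, 4, 1, 5]},
                      index=["both", "low_only", "spread", "fill"])
    cats = {"h1": "high", "h2": "high", "m1": "medium", "l1": "low"}
    return CountTable(df), cats


class TestNodeFractions:
    def test_fraction_shares(self, category_table):
        table, cats = category_table
        frac = node_settlement_fractions(table, cats)
        # "both": 0.3+0.3 high, 0.2 medium, 0 low -> (0.75, 0.25, 0)
        assert frac.loc["both", ["high", "medium", "low"]].tolist() == \
            pytest.approx([0.75, 0.25, 0.0])

    def test_category_exclusive_node(self, category_table):
        table, cats = category_table
        frac = node_settlement_fractions(table, cats)
        assert frac.loc["low_only", ["high", "medium", "low"]].tolist() == \
            pytest.approx([0.0, 0.0, 1.0])

    def test_fractions_sum_to_one(self, experiment):
        table, meta, tax, settled, truth = experiment
        frac = node_settlement_fractions(
            table, {s: truth.category_of_tetrapod["_".join(s.split("_")[:-1])]
                    for s in table.sample_ids})
        defined = frac[~frac["undefined"]]
        assert np.allclose(defined[["high", "medium", "low"]].sum(axis=1), 1.0)


class TestModuleComposition:
    def test_single_node_module_equals_node_fractions(self, category_table):
        table, cats = category_table
        part = ModulePartition({"both": 0, "low_only": 1, "spread": 1, "fill": 2}, 0.0)
        comp = module_settlement_composition(table, cats, part, 0)
        frac = node_settlement_fractions(table, cats)
        assert comp.tolist() == pytest.approx(
            frac.loc["both", ["high", "medium", "low"]].tolist())

    def test_composition_is_abundance_weighted_mean(self, category_table):
        table, cats = category_table
        part = ModulePartition({"both": 0, "low_only": 0, "spread": 0, "fill": 1}, 0.0)
        comp = module_settlement_composition(table, cats, part, 0)
        from settlenet.core_microbiome import relative_abundance
        rel = relative_abundance(table).loc[["both", "low_only", "spread"]]
        weights = rel.sum(axis=1)
        frac = node_settlement_fractions(table, cats).loc[
            ["both", "low_only", "spread"], ["high", "medium", "low"]]
        expected = (frac.mul(weights, axis=0).sum() / weights.sum())
        assert comp.tolist() == pytest.approx(expected.tolist())


class TestPurity:
    def test_dominant_category_above_threshold(self):
        comp = pd.Series({"high": 0.993, "medium": 0.007, "low": 0.0})
        assert label_module_purity(comp) == "high"

    def test_mixed_below_threshold(self):
        comp = pd.Series({"high": 0.5, "medium": 0.3, "low": 0.2})
        assert label_module_purity(comp) == "mixed"

    def test_threshold_one_requires_exclusivity(self):
        comp = pd.Series({"high": 0.999, "medium": 0.001, "low": 0.0})
        assert label_module_purity(comp, purity_threshold=1.0) == "mixed"


def _four_node():
    g = nx.Graph([(1, 3), (2, 3), (1, 2), (3, 4)])
    part = ModulePartition({1: "A", 2: "A", 3: "B", 4: "B"}, 0.0)
    return g, part


class TestCollapse:
    def test_cross_edges_counted(self):
        g, part = _four_node()
        mg = collapse_modules(g, part)
        assert mg.number_of_edges() == 1
        assert mg["A"]["B"]["weight"] == 2

    def test_no_cross_edges_gives_edgeless_graph(self):
        g = _two = nx.Graph([(1, 2), (3, 4)])
        part = ModulePartition({1: 0, 2: 0, 3: 1, 4: 1}, 0.0)
        mg = collapse_modules(g, part)
        assert mg.number_of_edges() == 0
        assert sum(d["n_members"] for _, d in mg.nodes(data=True)) == 4

    def test_edge_weights_conserve_cross_edge_count(self):
        rng = np.random.default_rng(2)
        g = nx.gnp_random_graph(20, 0.3, seed=4)
        part = ModulePartition({v: int(rng.integers(4)) for v in g.nodes}, 0.0)
        mg = collapse_modules(g, part)
        crossing = sum(1 for u, v in g.edges()
                       if part.assignment[u] != part.assignment[v])
        assert sum(d["weight"] for _, _, d in mg.edges(data=True)) == crossing


class TestBridging:
    def test_four_node_example(self):
        g, part = _four_node()
        assert bridging_nodes(g, part) == {1, 2, 3}

    def test_fully_intra_module_graph_has_none(self):
        g = nx.Graph([(1, 2), (3, 4)])
        part = ModulePartition({1: 0, 2: 0, 3: 1, 4: 1}, 0.0)
        assert bridging_nodes(g, part) == set()

    def test_every_cross_edge_endpoint_included(self):
        rng = np.random.default_rng(8)
        g = nx.gnp_random_graph(15, 0.25, seed=9)
        part = ModulePartition({v: int(rng.integers(3)) for v in g.nodes}, 0.0)
        bridge = bridging_nodes(g, part)
        for u, v in g.edges():
            if part.assignment[u] != part.assignment[v]:
                assert u in bridge and v in bridge


def _brute_betweenness(g):
    """Independent oracle: enumerate all shortest paths between every pair."""
    import itertools
    btw = dict.fromkeys(g.nodes, 0.0)
    for s, t in itertools.combinations(g.nodes, 2):
        try:
            length = nx.shortest_path_length(g, s, t)
        except nx.NetworkXNoPath:
            continue
        paths = [p for p in _all_paths_up_to(g, s, t, length) if len(p) - 1 == length]
        for v in g.nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            btw[v] += through / len(paths)
    return btw


def _all_paths_up_to(g, s, t, maxlen):
    stack = [(s, [s])]
    while stack:
        node, path = stack.pop()
        if node == t:
            yield path
            continue
        if len(path) > maxlen:
            continue
        for nb in g[node]:
            if nb not in path:
                stack.append((nb, path + [nb]))


class TestBetweennessDegree:
    def test_path_midpoint(self):
        bd = betweenness_degree(nx.path_graph(3))
        assert bd.loc[1, "betweenness"] == pytest.approx(1.0)

    def test_star_centre_counts_all_leaf_pairs(self):
        bd = betweenness_degree(nx.star_graph(4))
        assert bd.loc[0, "betweenness"] == pytest.approx(6.0)
        assert bd.loc[0, "degree"] == 4

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        g = nx.gnp_random_graph(n, 0.45, seed=seed)
        bd = betweenness_degree(g)
        oracle = _brute_betweenness(g)
        for v in g.nodes:
            assert bd.loc[v, "betweenness"] == pytest.approx(oracle[v], abs=1e-9)


class TestNodesOfInterest:
    @pytest.mark.parametrize("btw,deg,expected", [
        (10, 3, True), (10, 8, False), (0, 2, False), (3, 2, True)])
    def test_threshold_logic(self, btw, deg, expected):
        ann = pd.DataFrame({"betweenness": [btw], "degree": [deg]}, index=["v"])
        got = nodes_of_interest(ann, bridging={"v"}, betweenness_min=3,
                                degree_range=(2, 4))
        assert (("v" in got) is expected)

    def test_subset_of_bridging(self):
        ann = pd.DataFrame({"betweenness": [10, 10], "degree": [3, 3]},
                           index=["in_bridge", "not_bridge"])
        got = nodes_of_interest(ann, bridging={"in_bridge"})
        assert got == {"in_bridge"}


def _taxonomy_for(asvs, family_of):
    rows = {a: ("Bacteria", UNASSIGNED, UNASSIGNED, UNASSIGNED,
                family_of[a], UNASSIGNED, UNASSIGNED) for a in asvs}
    return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index",
                                                columns=list(RANKS)))


class TestExclusivity:
    def test_asv_level(self, category_table):
        table, cats = category_table
        excl = exclusive_taxa(table, cats, rank="asv")
        assert "low_only" in excl["low"]
        assert all("both" not in s for s in excl.values())

    def test_family_split_across_categories_not_exclusive(self):
        df = pd.DataFrame({"h": [5, 0, 1], "l": [0, 5, 1]}, index=["a1", "a2", "fill"])
        table = CountTable(df)
        cats = {"h": "high", "l": "low"}
        tax = _taxonomy_for(["a1", "a2", "fill"],
                            {"a1": "FamX", "a2": "FamX", "fill": "FamY"})
        excl = exclusive_taxa(table, cats, rank="family", taxonomy=tax)
        assert "FamX" not in excl["high"] and "FamX" not in excl["low"]
        # even though each member ASV individually is exclusive
        asv_excl = exclusive_taxa(table, cats, rank="asv")
        assert "a1" in asv_excl["high"] and "a2" in asv_excl["low"]


class TestRareTaxa:
    def test_abundant_family_excluded_and_partition(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.integers(1, 10, size=(6, 5)))
        df.iloc[0] += 5000  # dominant family
        df.index = [f"a{i}" for i in range(6)]
        table = CountTable(df)
        tax = _taxonomy_for(table.asv_ids, {a: f"Fam{i}" for i, a in
                                            enumerate(table.asv_ids)})
        rare, mat = rare_taxa(table, tax, cutoff=0.01)
        assert "Fam0" not in rare
        all_fams = {f"Fam{i}" for i in range(6)}
        assert rare <= all_fams
        from settlenet.core_microbiome import relative_abundance
        non_rare = all_fams - rare
        assert non_rare  # partition: rare + non-rare covers all families
        assert set(mat.index) == rare
        # log-transformed relative abundances are ln(x+1) of values in [0,1]
        assert (mat.to_numpy() <= np.log(2) + 1e-12).all()
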
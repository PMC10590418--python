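"""Pooling, transforms, Bray-Curtis, nMDS and PERMANOVA."""

import numpy as np
import pandas as pd
import pytest

from settlenet.community_stats import (DistanceMatrix, bray_curtis, log_transform,
                                       nmds, pairwise_permanova, permanova,
                                       pool_compartments)
from settlenet.io import DataError


class TestPooling:
    def test_pooled_counts_are_compartment_sums(self, compartment_setup):
        table, meta = compartment_setup
        pooled, pooled_meta = pool_compartments(table, meta)
        assert pooled.sample_ids == ["t0", "t1"]
        for tet in pooled.sample_ids:
            comps = [c for c in table.sample_ids if c.startswith(tet)]
            assert (pooled.counts[tet] == table.counts[comps].sum(axis=1)).all()
        assert set(pooled_meta.table["compartment"]) == {"pooled"}

    def test_total_reads_conserved(self, experiment):
        table, meta, *_ = experiment
        pooled, _ = pool_compartments(table, meta)
        assert pooled.matrix.sum() == table.matrix.sum()


class TestTransforms:
    def test_log_transform_closed_forms(self):
        arr = np.array([[0.0, 1.0, np.e - 1]])
        out = log_transform(arr)
        assert out[0, 0] == 0.0
        assert out[0, 1] == pytest.approx(np.log(2))
        assert out[0, 2] == pytest.approx(1.0)


class TestBrayCurtis:
    def test_identical_columns_distance_zero(self):
        d = bray_curtis(np.array([[3, 3], [1, 1]], dtype=float))
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_distance_one(self):
        d = bray_curtis(np.array([[5, 0], [0, 7]], dtype=float))
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_hand_example(self):
        # x=[2,2,0], y=[0,2,2]: 1 - 2*2/8 = 0.5
        d = bray_curtis(np.array([[2, 0], [2, 2], [0, 2]], dtype=float))
        assert d.values[0, 1] == pytest.approx(0.5)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(DataError):
            bray_curtis(np.array([[1, 0], [1, 0]], dtype=float))

    def test_bounds_and_symmetry_on_random_tables(self):
        rng = np.random.default_rng(3)
        mat = rng.integers(0, 50, size=(12, 8)) + 1
        d = bray_curtis(mat.astype(float))
        assert ((d.values >= 0) & (d.values <= 1)).all()
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0)


class TestNMDS:
    def test_exactly_embeddable_distances_reach_tiny_stress(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 2))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        dist = DistanceMatrix([f"s{i}" for i in range(6)], d)
        _, stress, _ = nmds(dist, k=2, n_restarts=4, seed=0)
        assert stress < 0.01

    def test_full_dimensional_embedding_is_near_perfect(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(5, 4))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        dist = DistanceMatrix([f"s{i}" for i in range(5)], d)
        _, stress, _ = nmds(dist, k=4, seed=0)
        assert stress < 0.01

    def test_stress_trace_is_non_increasing(self):
        rng = np.random.default_rng(2)
        mat = rng.integers(1, 40, size=(15, 9)).astype(float)
        dist = bray_curtis(mat)
        coords, stress, trace = nmds(dist, seed=0)
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))
        assert stress == pytest.approx(trace[-1])

    def test_reported_stress_matches_recomputation(self):
        from scipy.optimize import isotonic_regression
        from scipy.spatial.distance import pdist, squareform
        rng = np.random.default_rng(4)
        mat = rng.integers(1, 40, size=(15, 9)).astype(float)
        dist = bray_curtis(mat)
        coords, stress, _ = nmds(dist, seed=0)
        d = pdist(coords.to_numpy())
        delta = squareform(dist.values, checks=False)
        order = np.argsort(delta, kind="stable")
        disp = np.empty_like(d)
        disp[order] = isotonic_regression(d[order]).x
        disp *= np.sqrt((d ** 2).sum() / (disp ** 2).sum())
        recomputed = np.sqrt(((d - disp) ** 2).sum() / (d ** 2).sum())
        assert recomputed == pytest.approx(stress, abs=1e-8)

    def test_all_zero_distances_rejected(self):
        dist = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        with pytest.raises(DataError):
            nmds(dist)


def _two_cluster_distance(sep, n_per=10, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per, 3))
    X[n_per:] += sep
    d = np.linalg.norm(X[:, None] - X[None], axis=-1)
    return DistanceMatrix([f"s{i}" for i in range(2 * n_per)], d)


class TestPermanova:
    def test_separated_clusters_detected(self):
        dist = _two_cluster_distance(sep=5.0)
        res = permanova(dist, [0] * 10 + [1] * 10, n_perm=999, seed=1)
        assert res.p_perm <= 0.005
        assert res.R2 > 0.5

    def test_scale_invariance_of_F_and_p(self):
        dist = _two_cluster_distance(sep=1.0)
        scaled = DistanceMatrix(dist.sample_ids, dist.values * 7.5)
        groups = [0] * 10 + [1] * 10
        a = permanova(dist, groups, n_perm=99, seed=3)
        b = permanova(scaled, groups, n_perm=99, seed=3)
        assert a.pseudo_F == pytest.approx(b.pseudo_F)
        assert a.p_perm == b.p_perm

    def test_matches_reference_implementation_F(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova
        dist = _two_cluster_distance(sep=1.5, seed=5)
        groups = [0] * 10 + [1] * 10
        mine = permanova(dist, groups, n_perm=99, seed=0)
        theirs = sk_permanova(skbio.DistanceMatrix(dist.values, dist.sample_ids),
                              [str(g) for g in groups], permutations=99)
        assert mine.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_small_group_rejected(self):
        dist = _two_cluster_distance(sep=1.0)
        with pytest.raises(DataError, match="fewer than 2"):
            permanova(dist, [0] + [1] * 19)


class TestPairwise:
    def test_two_groups_reduce_to_single_permanova(self):
        dist = _two_cluster_distance(sep=2.0)
        groups = np.array([0] * 10 + [1] * 10)
        table = pairwise_permanova(dist, groups, n_perm=99, seed=4)
        single = permanova(dist, groups, n_perm=99, seed=4)
        assert len(table) == 1
        assert table.loc[0, "pseudo_F"] == pytest.approx(single.pseudo_F)

    def test_bonferroni_adjustment_definition(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(18, 4))
        d = np.linalg.norm(X[:, None] - X[None], axis=-1)
        dist = DistanceMatrix([f"s{i}" for i in range(18)], d)
        groups = np.repeat([0, 1, 2], 6)
        table = pairwise_permanova(dist, groups, n_perm=99, seed=0)
        assert len(table) == 3
        assert np.allclose(table["p_adjusted"],
                           np.minimum(1.0, table["p"] * 3))
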
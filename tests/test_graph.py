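import networkx as nx
import numpy as np
import pytest

from treescreen.graph import (
    UNLABELED,
    adjacency,
    build_semantic_graph,
    drop_edges,
    graph_density,
    read_graph,
    remove_feature_class,
    split_nodes,
    subset_training,
    write_graph,
)


def _random_graph(rng, m=12, n=6, p=0.3):
    Z = (rng.random((m, n)) < p).astype(int)
    return Z, build_semantic_graph(Z)


class TestBuildSemanticGraph:
    def test_full_cohort_vertex_count(self, small_cohort):
        g = build_semantic_graph(small_cohort.Z)
        assert g.n_vertices == small_cohort.n_subjects + 98

    def test_study_scale_graph_is_904_vertices(self):
        Z = np.zeros((806, 98), dtype=int)
        g = build_semantic_graph(Z)
        assert g.n_vertices == 904

    def test_identity_matrix(self):
        g = build_semantic_graph(np.eye(2, dtype=int))
        assert g.n_vertices == 4
        assert g.n_edges == 2

    def test_all_zero_matrix_keeps_isolated_vertices(self):
        g = build_semantic_graph(np.zeros((3, 4), dtype=int))
        assert g.n_vertices == 7
        assert g.n_edges == 0

    def test_edge_count_equals_popcount(self, rng):
        for _ in range(20):
            Z, g = _random_graph(rng)
            assert g.n_edges == int(Z.sum())

    def test_rejects_nonbinary(self):
        with pytest.raises(ValueError):
            build_semantic_graph(np.array([[0, 2]]))

    def test_coding_matrix_roundtrip(self, rng):
        Z, g = _random_graph(rng)
        assert np.array_equal(g.to_coding_matrix(), Z)


class TestAdjacency:
    def test_single_edge_normalization(self):
        g = build_semantic_graph(np.array([[1]]))
        pair = adjacency(g)
        assert pair.A_hat[0, 1] == pytest.approx(1.0)

    def test_star_normalization(self):
        # one feature linked to 4 images: A_hat(feature, image) = 1/sqrt(4*1)
        g = build_semantic_graph(np.ones((4, 1), dtype=int))
        pair = adjacency(g)
        assert pair.A_hat[4, 0] == pytest.approx(0.5)
        assert pair.A_hat[0, 4] == pytest.approx(0.5)

    def test_isolated_vertex_zero_row(self):
        Z = np.array([[1, 0], [0, 0]])
        g = build_semantic_graph(Z)
        pair = adjacency(g)
        dense = pair.A_hat.toarray()
        assert np.all(dense[1] == 0) and np.all(dense[:, 1] == 0)
        assert np.all(dense[3] == 0) and np.all(dense[:, 3] == 0)

    def test_symmetry_and_spectral_radius(self, rng):
        for _ in range(10):
            Z, g = _random_graph(rng)
            A_hat = adjacency(g).A_hat.toarray()
            assert np.allclose(A_hat, A_hat.T)
            eigs = np.linalg.eigvalsh(A_hat)
            assert np.abs(eigs).max() <= 1.0 + 1e-9

    def test_self_loop_convention(self):
        g = build_semantic_graph(np.array([[1]]))
        pair = adjacency(g, self_loops=True)
        # A+I on a single edge: degrees 2, off-diagonal 1/2, diagonal 1/2
        assert pair.A_hat[0, 0] == pytest.approx(0.5)
        assert pair.A_hat[0, 1] == pytest.approx(0.5)

    def test_matches_networkx(self, rng):
        Z, g = _random_graph(rng)
        G = nx.Graph()
        G.add_nodes_from(range(g.n_vertices))
        ii, jj = g.edge_arrays()
        G.add_edges_from(zip(ii, jj + g.n_images))
        expected = nx.to_numpy_array(G, nodelist=range(g.n_vertices))
        assert np.array_equal(adjacency(g).A.toarray(), expected)


class TestGraphDensity:
    def test_study_scale_density(self):
        """904 vertices / 15379 edges: density 0.0377, i.e. 0.04 at 2 dp."""
        Z = np.zeros((806, 98), dtype=int)
        Z.ravel()[:15379] = 1  # exactly 15379 edges
        g = build_semantic_graph(Z)
        d = graph_density(g)
        assert d == pytest.approx(0.0377, abs=5e-4)
        assert round(d, 2) == 0.04

    def test_complete_bipartite(self):
        g = build_semantic_graph(np.ones((2, 2), dtype=int))
        assert graph_density(g) == pytest.approx(4 / 6)

    def test_edgeless(self):
        g = build_semantic_graph(np.zeros((1, 1), dtype=int))
        assert graph_density(g) == 0.0

    def test_matches_networkx(self, rng):
        Z, g = _random_graph(rng)
        G = nx.Graph()
        G.add_nodes_from(range(g.n_vertices))
        ii, jj = g.edge_arrays()
        G.add_edges_from(zip(ii, jj + g.n_images))
        assert graph_density(g) == pytest.approx(nx.density(G))


class TestDropEdges:
    def test_keep_all(self, rng):
        _, g = _random_graph(rng)
        assert drop_edges(g, 1.0, seed=0).edges == g.edges

    def test_exact_count(self, rng):
        Z = np.zeros((10, 10), dtype=int)
        Z.ravel()[:100] = 1
        g = build_semantic_graph(Z)
        assert drop_edges(g, 0.8, seed=0).n_edges == 80

    def test_remains_bipartite_subset(self, rng):
        for seed in range(50):
            Z, g = _random_graph(rng)
            out = drop_edges(g, 0.5, seed=seed)
            assert out.edges <= g.edges
            assert out.n_edges == round(0.5 * g.n_edges)
            assert out.n_vertices == g.n_vertices

    def test_invalid_fraction(self, rng):
        _, g = _random_graph(rng)
        with pytest.raises(ValueError):
            drop_edges(g, 0.0, seed=0)


class TestRemoveFeatureClass:
    def test_leaf_and_flower_leaves_95(self, catalog, small_cohort):
        g = build_semantic_graph(small_cohort.Z)
        out = remove_feature_class(g, catalog, "leaf and flower")
        assert out.n_features == 95
        assert out.n_images == g.n_images

    def test_canopy_leaves_79(self, catalog, small_cohort):
        g = build_semantic_graph(small_cohort.Z)
        assert remove_feature_class(g, catalog, "canopy").n_features == 79

    def test_unknown_class(self, catalog, small_cohort):
        g = build_semantic_graph(small_cohort.Z)
        with pytest.raises(KeyError):
            remove_feature_class(g, catalog, "nonexistent")

    def test_equals_column_deleted_rebuild(self, catalog, small_cohort):
        """Removing a class in the graph == deleting its columns in Z."""
        g = build_semantic_graph(small_cohort.Z)
        for cls in ("overall", "canopy", "attachment"):
            out = remove_feature_class(g, catalog, cls)
            keep = [
                j for j in range(98) if j not in set(catalog.class_indices(cls))
            ]
            rebuilt = build_semantic_graph(small_cohort.Z[:, keep])
            assert out.edges == rebuilt.edges
            assert out.n_features == rebuilt.n_features


class TestSplits:
    def test_study_scale_split(self):
        train, test = split_nodes(806, 0.8, seed=0)
        assert int(train.sum()) == 645
        assert int(test.sum()) == 161

    def test_small_split(self):
        train, test = split_nodes(10, 0.8, seed=0)
        assert int(train.sum()) == 8 and int(test.sum()) == 2

    def test_masks_partition(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 200))
            frac = float(rng.uniform(0.2, 0.9))
            if not 0 < round(frac * n) < n:
                continue
            train, test = split_nodes(n, frac, seed=int(rng.integers(1 << 30)))
            assert np.array_equal(train | test, np.ones(n, dtype=bool))
            assert not np.any(train & test)

    def test_degenerate_split_raises(self):
        with pytest.raises(ValueError):
            split_nodes(3, 0.01, seed=0)

    @pytest.mark.parametrize(
        "fraction,expected", [(1.0, 645), (0.9, 580), (0.8, 516),
                              (0.7, 451), (0.6, 387), (0.5, 322)]
    )
    def test_subset_floor_counts(self, fraction, expected):
        train, _ = split_nodes(806, 0.8, seed=1)
        sub = subset_training(train, fraction, seed=2)
        assert int(sub.sum()) == expected
        assert np.all(train[sub])  # subset of the original training mask

    def test_subset_identity_at_one(self):
        train, _ = split_nodes(20, 0.8, seed=1)
        assert np.array_equal(subset_training(train, 1.0, seed=5), train)


def test_graph_serialization_roundtrip(tmp_path, small_cohort):
    g = build_semantic_graph(small_cohort.Z, labels=small_cohort.labels)
    write_graph(g, tmp_path / "edges.tsv", tmp_path / "vertices.csv")
    back = read_graph(tmp_path / "edges.tsv", tmp_path / "vertices.csv")
    assert back.edges == g.edges
    assert back.image_ids == g.image_ids
    assert back.feature_ids == g.feature_ids
    assert np.array_equal(back.labels, g.labels)
    assert UNLABELED not in back.labels[: small_cohort.n_subjects]
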
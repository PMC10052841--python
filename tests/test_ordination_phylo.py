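import numpy as np
import pytest
from scipy.cluster.hierarchy import average as upgma_linkage
from scipy.spatial import procrustes
from scipy.spatial.distance import squareform

from dipkit.io_formats import DistanceMatrix
from dipkit.ordination_phylo import classical_mds, nj_tree, pca


class TestPca:
    def test_rank_one_matrix(self):
        X = np.outer(np.arange(5, dtype=float), np.array([1.0, 2.0, 3.0]))
        r = pca(X, n_components=2)
        assert r.explained_pct[0] == pytest.approx(100.0)
        assert r.explained_pct[1] == pytest.approx(0.0, abs=1e-9)

    def test_matches_covariance_eigendecomposition(self):
        """Coordinates reproduce the eigen-decomposition of the covariance
        matrix on a 5x3 toy."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(5, 3))
        r = pca(X, n_components=3)
        Xc = X - X.mean(axis=0)
        w, V = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        np.testing.assert_allclose(np.abs(r.coordinates),
                                   np.abs(Xc @ V), atol=1e-10)
        np.testing.assert_allclose(r.explained_pct, 100 * w / w.sum(), atol=1e-10)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 4))
        r = pca(X, n_components=4)
        for k in range(4):
            nz = np.flatnonzero(np.abs(r.loadings[:, k]) > 1e-12)
            assert r.loadings[nz[0], k] >= 0

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 6))
        perm = rng.permutation(10)
        r1 = pca(X, 3)
        r2 = pca(X[perm], 3)
        np.testing.assert_allclose(r1.explained_pct, r2.explained_pct, atol=1e-10)
        np.testing.assert_allclose(r1.coordinates[perm], r2.coordinates, atol=1e-8)

    def test_constant_matrix_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            r = pca(np.ones((4, 3)), 2)
        assert np.all(r.explained_pct == 0)

    def test_missing_values_mean_imputed(self):
        X = np.array([[1.0, 2.0], [np.nan, 4.0], [3.0, 6.0]])
        r = pca(X, 1)
        assert np.isfinite(r.coordinates).all()

    def test_explained_percentages_monotone(self):
        rng = np.random.default_rng(7)
        r = pca(rng.normal(size=(20, 8)), 8)
        assert np.all(np.diff(r.explained_pct) <= 1e-10)
        assert r.explained_pct.sum() <= 100 + 1e-9


class TestClassicalMds:
    def test_recovers_planted_plane_configuration(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(6, 2))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        C = classical_mds(DistanceMatrix([f"p{i}" for i in range(6)], D), 2)
        _, _, disparity = procrustes(X, C)
        assert disparity < 1e-9

    def test_zero_matrix(self):
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            C = classical_mds(DistanceMatrix(list("abc"), np.zeros((3, 3))), 2)
        assert np.all(C == 0)

    def test_duplicate_point_maps_identically(self):
        X = np.array([[0.0, 0], [1, 0], [0, 1], [1, 0]])
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        C = classical_mds(DistanceMatrix(list("abcd"), D), 2)
        np.testing.assert_allclose(C[1], C[3], atol=1e-10)

    def test_mds_of_pca_scores_reproduces_them(self):
        """Classical MDS on Euclidean distances between PCA scores gives
        the same configuration up to rotation."""
        rng = np.random.default_rng(9)
        scores = pca(rng.normal(size=(10, 4)), 2).coordinates
        D = np.sqrt(((scores[:, None] - scores[None]) ** 2).sum(-1))
        C = classical_mds(DistanceMatrix([str(i) for i in range(10)], D), 2)
        _, _, disparity = procrustes(scores, C)
        assert disparity < 1e-12


def _additive_matrix():
    # tree ((A:1,B:2):3,(C:4,D:5)) over the central edge of length 3
    labels = ["A", "B", "C", "D"]
    dist = {("A", "B"): 3, ("A", "C"): 8, ("A", "D"): 9,
            ("B", "C"): 9, ("B", "D"): 10, ("C", "D"): 9}
    M = np.zeros((4, 4))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                M[i, j] = M[j, i] = dist[(a, b)]
    return DistanceMatrix(labels, M)


class TestNj:
    def test_planted_additive_tree_recovered_exactly(self):
        t = nj_tree(_additive_matrix())
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in t.taxon_namespace}
        want = {("A", "B"): 3, ("A", "C"): 8, ("A", "D"): 9,
                ("B", "C"): 9, ("B", "D"): 10, ("C", "D"): 9}
        for (a, b), v in want.items():
            assert pdm.patristic_distance(taxa[a], taxa[b]) == pytest.approx(v)

    def test_three_taxa_closed_form(self):
        # three-point formulas: la = (dab + dac - dbc) / 2 etc.
        M = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        t = nj_tree(DistanceMatrix(["a", "b", "c"], M))
        lengths = {l.taxon.label: l.edge.length for l in t.leaf_node_iter()}
        assert lengths["a"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["b"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 10 - 5) / 2)

    def test_taxon_order_invariance(self):
        d = _additive_matrix()
        perm = [2, 0, 3, 1]
        d2 = DistanceMatrix([d.labels[i] for i in perm],
                            d.values[np.ix_(perm, perm)])
        t1 = nj_tree(d)
        t2 = nj_tree(d2)
        import dendropy

        tns = dendropy.TaxonNamespace()
        a = dendropy.Tree.get(data=t1.as_string(schema="newick"),
                              schema="newick", taxon_namespace=tns)
        b = dendropy.Tree.get(data=t2.as_string(schema="newick"),
                              schema="newick", taxon_namespace=tns)
        a.encode_bipartitions()
        b.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(a, b) == 0

    def test_ultrametric_matches_upgma_topology(self):
        """On an ultrametric matrix NJ and UPGMA give the same topology."""
        rng = np.random.default_rng(10)
        # build ultrametric distances from a random hierarchical clustering
        X = rng.normal(size=(7, 3))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        Z = upgma_linkage(squareform(D, checks=False))
        from scipy.cluster.hierarchy import cophenet

        U = squareform(cophenet(Z))
        labels = [f"t{i}" for i in range(7)]
        t = nj_tree(DistanceMatrix(labels, U))
        # UPGMA topology from the linkage: check NJ reproduces the first
        # UPGMA merge as a cherry
        first = sorted(int(x) for x in Z[0, :2])
        import dendropy

        leaf = {l.taxon.label: l for l in t.leaf_node_iter()}
        a = leaf[f"t{first[0]}"]
        b = leaf[f"t{first[1]}"]
        assert a.parent_node is b.parent_node  # sisters in the NJ tree

    def test_two_taxa_edge_case(self):
        with pytest.warns(UserWarning, match="2 taxa"):
            t = nj_tree(DistanceMatrix(["a", "b"],
                                       np.array([[0.0, 2.0], [2.0, 0.0]])))
        assert sum(1 for _ in t.leaf_node_iter()) == 2

    def test_negative_branch_flooring(self):
        # a non-additive matrix that produces a negative NJ branch
        M = np.array([
            [0, 1, 10, 10],
            [1, 0, 10, 10],
            [10, 10, 0, 0.1],
            [10, 10, 0.1, 0],
        ])
        t = nj_tree(DistanceMatrix(list("abcd"), M))
        assert all((e.length or 0) >= 0 for e in t.edges())
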
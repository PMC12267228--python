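"""Spot preprocessing, PCA, graph clustering and the bimod marker test."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score, silhouette_score

from carcinomap import st_core
from carcinomap.datatypes import SpotDataset, ValidationError
from carcinomap.st_core import (
    EmptyDatasetError,
    KnnGraph,
    bimod_lrt,
    build_knn_graph,
    canonicalize_labels,
    cluster_graph,
    correct_batch,
    embed_2d,
    find_markers_bimod,
    normalize_log,
    qc_filter,
    run_pca,
    select_hvg,
)


def _toy_dataset(counts):
    counts = np.asarray(counts)
    g, s = counts.shape
    spot_ids = np.array([f"s{i}" for i in range(s)])
    coords = pd.DataFrame(
        {
            "array_row": np.zeros(s, int), "array_col": np.arange(s),
            "pixel_x": np.arange(s, dtype=float), "pixel_y": np.zeros(s),
        },
        index=pd.Index(spot_ids, name="barcode"),
    )
    return SpotDataset(
        counts=counts, gene_ids=np.array([f"g{i}" for i in range(g)]),
        spot_ids=spot_ids, coords=coords,
        sample_label=np.array(["b0"] * s),
    )


class TestQCFilter:
    def test_umi_threshold_hand_count(self):
        ds = _toy_dataset(np.array([[10, 100, 1000]]))
        kept, metrics = qc_filter(ds, min_umi=50)
        assert kept.n_spots == 2
        assert list(metrics["kept"]) == [False, True, True]

    def test_zero_thresholds_identity_and_idempotence(self, st_small):
        once, _ = qc_filter(st_small, 0, 0)
        assert once.n_spots == st_small.n_spots
        again, _ = qc_filter(*[qc_filter(st_small, 1, 1)[0]], 1, 1)
        assert again.n_spots == qc_filter(st_small, 1, 1)[0].n_spots

    def test_planted_dead_spots_removed(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(2.0, size=(50, 40))
        dead = [3, 11, 19, 27, 35]
        counts[:, dead] = 0
        ds = _toy_dataset(counts)
        kept, metrics = qc_filter(ds, min_umi=1)
        assert kept.n_spots == 35
        assert sorted(np.flatnonzero(~metrics["kept"].to_numpy())) == dead

    def test_all_removed_raises(self):
        ds = _toy_dataset(np.array([[1, 1]]))
        with pytest.raises(EmptyDatasetError):
            qc_filter(ds, min_umi=10)


class TestNormalizeLog:
    def test_closed_form_value(self):
        counts = np.zeros((3, 1), dtype=int)
        counts[0, 0] = 1
        counts[1, 0] = 9999
        ds = normalize_log(_toy_dataset(counts), scale_factor=1e4)
        # spot total 1e4, count 1 -> log(1 + 1) = log 2
        assert np.isclose(ds.layers["lognorm"][0, 0], np.log(2.0))
        assert ds.layers["lognorm"][2, 0] == 0.0  # count 0 -> 0

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(3.0, size=(30, 4)) + 1
        doubled = counts.copy()
        doubled[:, 2] *= 2
        a = normalize_log(_toy_dataset(counts)).layers["lognorm"]
        b = normalize_log(_toy_dataset(doubled)).layers["lognorm"]
        np.testing.assert_allclose(a[:, 2], b[:, 2], atol=1e-12)

    def test_zero_total_spot_raises(self):
        ds = _toy_dataset(np.array([[1, 0], [2, 0]]))
        with pytest.raises(ValidationError, match="zero-total"):
            normalize_log(ds)


class TestSelectHVG:
    def test_all_genes_when_n_top_is_G(self, st_small):
        idx = select_hvg(st_small, st_small.n_genes)
        assert len(idx) == st_small.n_genes

    def test_planted_high_variance_markers_recovered(self):
        """Markers at fold 8 dominate the variance ranking."""
        from carcinomap import syndata

        cfg = syndata.STSimConfig(
            n_spots_per_cluster=100, n_genes=2000, n_markers_per_cluster=17,
            marker_fold=8.0, grid_shape=(15, 20), n_switch_genes=0, seed=2,
        )
        ds = normalize_log(syndata.generate_st_dataset(cfg))
        top100 = set(select_hvg(ds, 100))
        planted = set(
            np.flatnonzero(ds.gene_truth["marker_home_cluster"].to_numpy() >= 0)
        )
        assert len(planted) >= 50
        assert len(top100 & planted) >= 0.9 * min(len(planted), 50)

    def test_constant_gene_never_selected(self):
        counts = np.vstack([np.full(5, 3), [1, 5, 2, 9, 4], [7, 1, 8, 2, 6]])
        ds = normalize_log(_toy_dataset(counts))
        idx = select_hvg(ds, 2)
        assert 0 not in idx


class TestPCA:
    def test_exact_rank_reconstruction(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(20, 2)) @ rng.normal(size=(2, 10))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_pca(base, n_pcs=2)
        recon = res.scores @ res.components + base.mean(0)
        np.testing.assert_allclose(recon, base, atol=1e-8)

    def test_explained_variance_sorted(self):
        rng = np.random.default_rng(4)
        res = run_pca(rng.normal(size=(40, 12)), n_pcs=8)
        assert np.all(np.diff(res.explained_variance) <= 1e-12)

    def test_agrees_with_eigendecomposition_oracle(self):
        """Scores match (up to sign) an independent covariance
        eigendecomposition on a 20x10 matrix."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 10))
        res = run_pca(X, n_pcs=5)
        Xc = X - X.mean(0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / (X.shape[0] - 1))
        order = np.argsort(evals)[::-1][:5]
        oracle_scores = Xc @ evecs[:, order]
        for c in range(5):
            direct = res.scores[:, c]
            assert (
                np.allclose(direct, oracle_scores[:, c], atol=1e-8)
                or np.allclose(direct, -oracle_scores[:, c], atol=1e-8)
            )
        np.testing.assert_allclose(
            res.explained_variance, evals[order], atol=1e-8
        )


class TestCorrectBatch:
    def test_single_batch_identity(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 3))
        np.testing.assert_array_equal(correct_batch(X, ["a"] * 10), X)

    def test_constant_offset_removed(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 4))
        shifted = X.copy()
        shifted[20:] += np.array([5.0, -3.0, 2.0, 0.7])
        labels = ["a"] * 20 + ["b"] * 20
        out = correct_batch(shifted, labels)
        gap = out[:20].mean(0) - out[20:].mean(0)
        assert np.linalg.norm(gap) < 1e-8

    def test_within_batch_distances_preserved(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 5))
        labels = np.array(["a"] * 15 + ["b"] * 15)
        out = correct_batch(X, labels)
        for b in ("a", "b"):
            sub_in = X[labels == b]
            sub_out = out[labels == b]
            d_in = np.linalg.norm(sub_in[:, None] - sub_in[None], axis=-1)
            d_out = np.linalg.norm(sub_out[:, None] - sub_out[None], axis=-1)
            np.testing.assert_allclose(d_in, d_out, atol=1e-10)


class TestKnnGraph:
    def test_collinear_union_symmetrization(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        g = build_knn_graph(pts, k=1)
        deg = np.bincount(g.edges.ravel(), minlength=3)
        assert deg[1] == 2  # middle node picked up from both sides

    def test_no_self_loops_and_weight_range(self):
        rng = np.random.default_rng(9)
        g = build_knn_graph(rng.normal(size=(50, 3)), k=5)
        assert np.all(g.edges[:, 0] != g.edges[:, 1])
        assert np.all((g.weights >= 0) & (g.weights <= 1))
        assert np.all(g.distances >= 0)

    def test_invalid_k(self):
        with pytest.raises(ValidationError):
            build_knn_graph(np.zeros((5, 2)), k=0)
        with pytest.raises(ValidationError):
            build_knn_graph(np.zeros((5, 2)), k=5)


def _clique_graph():
    # two 4-cliques, no inter-clique edges
    edges = []
    for base in (0, 4):
        for i in range(4):
            for j in range(i + 1, 4):
                edges.append((base + i, base + j))
    edges = np.array(edges)
    return KnnGraph(
        n_nodes=8, edges=edges, weights=np.ones(len(edges)),
        distances=np.ones(len(edges)), k=3,
    )


class TestClusterGraph:
    def test_disconnected_cliques_split(self):
        assignment = cluster_graph(_clique_graph(), resolution=1.0)
        labels = assignment.labels
        assert assignment.n_clusters == 2
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1

    def test_resolution_to_zero_single_cluster(self):
        rng = np.random.default_rng(10)
        g = build_knn_graph(rng.normal(size=(30, 2)), k=5)
        assignment = cluster_graph(g, resolution=1e-9)
        assert assignment.n_clusters == 1

    def test_planted_cluster_recovery(self, st_small):
        hvg = select_hvg(st_small, 200)
        sub = st_small.subset_genes(hvg)
        pca = run_pca(sub.layers["lognorm"].T, n_pcs=10)
        g = build_knn_graph(pca.scores, k=10)
        assignment = cluster_graph(g, resolution=0.1)
        ari = adjusted_rand_score(
            st_small.truth["cluster"], assignment.labels
        )
        assert ari >= 0.9

    def test_canonical_label_order(self):
        labels = canonicalize_labels(np.array([5, 5, 5, 2, 2, 9]))
        assert list(labels) == [0, 0, 0, 1, 1, 2]

    def test_empty_graph_raises(self):
        g = KnnGraph(n_nodes=0, edges=np.zeros((0, 2), int),
                     weights=np.zeros(0), distances=np.zeros(0), k=1)
        with pytest.raises(ValidationError):
            cluster_graph(g)


class TestEmbed2D:
    @pytest.mark.parametrize("method", ["umap", "tsne"])
    def test_shape_and_determinism(self, method):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(40, 5))
        a = embed_2d(X, method=method, seed=3)
        b = embed_2d(X, method=method, seed=3)
        assert a.shape == (40, 2)
        np.testing.assert_array_equal(a, b)

    def test_separated_gaussians_keep_silhouette(self):
        rng = np.random.default_rng(12)
        X = np.vstack(
            [rng.normal(loc=c, scale=0.3, size=(40, 6)) for c in (0, 5, 10)]
        )
        labels = np.repeat([0, 1, 2], 40)
        emb = embed_2d(X, method="umap", seed=0)
        assert silhouette_score(emb, labels) > 0.5

    def test_unknown_method(self):
        with pytest.raises(ValidationError):
            embed_2d(np.zeros((5, 2)), method="pca")


class TestBimodLRT:
    def test_identical_groups_null(self):
        x = np.array([0, 0, 1.5, 2.0, 0, 2.5])
        stat, p = bimod_lrt(x, x.copy())
        assert stat == 0.0 and p == 1.0

    def test_total_separation_tiny_p(self):
        rng = np.random.default_rng(13)
        zeros = np.zeros(50)
        pos = rng.normal(2.0, 0.2, size=50)
        _, p = bimod_lrt(zeros, pos)
        assert p < 1e-10

    def test_null_pvalues_uniform(self):
        """p-values from null zero-inflated-normal data pass a KS test
        against U(0,1)."""
        rng = np.random.default_rng(14)
        n, reps = 150, 400
        pvals = []
        for _ in range(reps):
            detect = rng.random(2 * n) < 0.6
            x = np.where(detect, rng.normal(2.0, 0.5, 2 * n), 0.0)
            pvals.append(bimod_lrt(x[:n], x[n:])[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_markers_in_top50(self, st_small):
        table = find_markers_bimod(
            st_small, st_small.truth["cluster"].to_numpy()
        )
        gt = st_small.gene_truth
        recovered = total = 0
        for c in range(3):
            planted = set(
                gt.index[gt["marker_home_cluster"] == c]
            )
            top = st_core.top_markers(table, c, n=50)
            recovered += len(planted & set(top["gene"]))
            total += len(planted)
        assert recovered >= 0.9 * total

    def test_small_cluster_skipped_with_warning(self, st_small):
        labels = np.zeros(st_small.n_spots, dtype=int)
        labels[:2] = 1  # below the 3-spot minimum
        with pytest.warns(UserWarning, match="fewer than"):
            table = find_markers_bimod(st_small, labels)
        assert set(table["cluster"]) == {0}
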
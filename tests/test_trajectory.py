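"""Diffusion pseudotime, cluster connectivity, PSTD and arborescence."""

import itertools

import numpy as np
import pytest
from scipy.stats import spearmanr

from carcinomap.datatypes import ValidationError
from carcinomap.st_core import KnnGraph
from carcinomap.trajectory import (
    ClusterNodes,
    build_diffusion,
    cluster_connectivity,
    connect_components,
    diffusion_pseudotime,
    infer_trajectory,
    make_cluster_nodes,
    min_arborescence,
    pstd,
)


def _path_graph(n=10):
    edges = np.array([(i, i + 1) for i in range(n - 1)])
    return KnnGraph(
        n_nodes=n, edges=edges, weights=np.ones(n - 1),
        distances=np.ones(n - 1), k=1,
    )


def _two_cliques():
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


class TestDiffusionOperator:
    def test_rows_stochastic_and_leading_eigenvalue(self):
        op = build_diffusion(_path_graph(), n_components=5)
        np.testing.assert_allclose(op.transition.sum(axis=1), 1.0, atol=1e-10)
        assert abs(op.eigenvalues[0] - 1.0) < 1e-8
        assert np.all(np.abs(op.eigenvalues) <= 1.0 + 1e-10)

    def test_second_eigenvector_monotone_on_path(self):
        op = build_diffusion(_path_graph(), n_components=5)
        psi2 = op.eigenvectors[:, 1]
        diffs = np.diff(psi2)
        assert np.all(diffs > 0) or np.all(diffs < 0)

    def test_disconnected_uses_largest_component(self):
        g = _two_cliques()
        g.edges = np.vstack([g.edges, [[0, 4]]])  # connect, then cut again
        g = _two_cliques()
        extra = KnnGraph(
            n_nodes=9, edges=g.edges, weights=g.weights,
            distances=g.distances, k=3,
        )  # node 8 isolated
        with pytest.warns(UserWarning, match="components"):
            op = build_diffusion(extra, n_components=3)
        assert 8 not in op.nodes


class TestDiffusionPseudotime:
    def test_root_is_zero_and_path_monotone(self):
        op = build_diffusion(_path_graph(), n_components=9)
        tau = diffusion_pseudotime(op, root_spot=0)
        assert tau[0] == 0.0
        assert np.all(np.diff(tau) > 0)

    def test_gradient_recovery_on_default_simulation(self, st_default):
        """DPT correlates with the planted latent time (Spearman >= 0.9)."""
        traj = infer_trajectory(
            st_default, st_default.truth["cluster"].to_numpy(), root_cluster=0
        )
        rho = spearmanr(
            traj.pseudotime, st_default.truth["latent_time"]
        ).statistic
        assert rho >= 0.9

    def test_connect_components_bridges(self):
        pts = np.vstack([np.zeros((4, 2)), np.ones((4, 2)) * 10])
        pts += np.arange(8)[:, None] * 0.01
        g = _two_cliques()
        bridged = connect_components(g, pts)
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components as cc

        i, j = bridged.edges[:, 0], bridged.edges[:, 1]
        adj = coo_matrix((np.ones(len(i)), (i, j)), shape=(8, 8))
        n_comp, _ = cc(adj, directed=False)
        assert n_comp == 1


class TestClusterConnectivity:
    def test_disconnected_cliques_zero_offdiag(self):
        labels = np.repeat([0, 1], 4)
        conn = cluster_connectivity(_two_cliques(), labels)
        assert conn[0, 1] == 0.0 and conn[1, 0] == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(60, 3))
        from carcinomap.st_core import build_knn_graph

        g = build_knn_graph(pts, k=5)
        labels = rng.integers(0, 3, size=60)
        conn = cluster_connectivity(g, labels)
        np.testing.assert_allclose(conn, conn.T, atol=1e-12)

    def test_adjacent_planted_clusters_more_connected(self, st_default):
        """Clusters laid out A-B-C along the gradient: neighbors link more
        strongly than the distal pair."""
        from carcinomap.st_core import build_knn_graph, run_pca

        X = st_default.layers["lognorm"].T
        pca = run_pca(X, n_pcs=20)
        g = build_knn_graph(pca.scores, k=15)
        labels = st_default.truth["cluster"].to_numpy()
        conn = cluster_connectivity(g, labels)
        assert conn[0, 1] >= conn[0, 2]
        assert conn[1, 2] >= conn[0, 2]


def _toy_nodes():
    return ClusterNodes(
        cluster_ids=np.arange(3),
        expr_centroid=np.array([[0.0, 0], [1, 0], [5, 0]]),
        spatial_centroid=np.array([[0.0, 0], [10, 0], [11, 0]]),
        mean_tau=np.array([0.1, 0.5, 0.9]),
        sizes=np.array([5, 5, 5]),
    )


class TestPSTD:
    def test_alpha_one_reduces_to_expression(self):
        nodes = _toy_nodes()
        D = pstd(nodes, alpha=1.0)
        d = np.linalg.norm(
            nodes.expr_centroid[:, None] - nodes.expr_centroid[None], axis=-1
        )
        off = ~np.eye(3, dtype=bool)
        dn = (d - d[off].min()) / (d[off].max() - d[off].min())
        finite = np.isfinite(D)
        np.testing.assert_allclose(D[finite], dn[finite], atol=1e-12)

    def test_alpha_zero_reduces_to_spatial(self):
        nodes = _toy_nodes()
        D = pstd(nodes, alpha=0.0)
        d = np.linalg.norm(
            nodes.spatial_centroid[:, None] - nodes.spatial_centroid[None],
            axis=-1,
        )
        off = ~np.eye(3, dtype=bool)
        dn = (d - d[off].min()) / (d[off].max() - d[off].min())
        finite = np.isfinite(D)
        np.testing.assert_allclose(D[finite], dn[finite], atol=1e-12)

    def test_direction_masking(self):
        D = pstd(_toy_nodes(), alpha=0.5)
        tau = _toy_nodes().mean_tau
        for i in range(3):
            for j in range(3):
                if tau[i] < tau[j]:
                    assert np.isfinite(D[i, j])
                    assert np.isinf(D[j, i])

    def test_degenerate_distances_warn(self):
        nodes = _toy_nodes()
        nodes.spatial_centroid = np.zeros((3, 2))
        with pytest.warns(UserWarning, match="degenerate"):
            pstd(nodes, alpha=0.0)


def _brute_force_arborescence(dist, root):
    """Enumerate all parent functions; min total weight of valid trees."""
    n = dist.shape[0]
    non_root = [v for v in range(n) if v != root]
    best = np.inf
    best_edges = None
    choices = [
        [u for u in range(n) if u != v and np.isfinite(dist[u, v])]
        for v in non_root
    ]
    for assignment in itertools.product(*choices):
        parent = dict(zip(non_root, assignment))
        # validity: every node reaches the root following parents
        ok = True
        for v in non_root:
            seen = set()
            cur = v
            while cur != root:
                if cur in seen or cur not in parent:
                    ok = False
                    break
                seen.add(cur)
                cur = parent[cur]
            if not ok:
                break
        if not ok:
            continue
        w = sum(dist[parent[v], v] for v in non_root)
        if w < best - 1e-12:
            best = w
            best_edges = sorted((parent[v], v) for v in non_root)
    return best, best_edges


class TestMinArborescence:
    def test_two_nodes(self):
        D = np.array([[np.inf, 0.7], [np.inf, np.inf]])
        edges, total = min_arborescence(D, root=0)
        assert edges == [(0, 1, 0.7)]
        assert total == pytest.approx(0.7)

    def test_matches_brute_force_on_random_instances(self):
        """100 seeded random <=5-node instances agree with exhaustive
        enumeration of all parent functions."""
        rng = np.random.default_rng(0)
        for trial in range(100):
            n = int(rng.integers(2, 6))
            D = rng.random((n, n)) * 10
            np.fill_diagonal(D, np.inf)
            # randomly forbid some edges but keep root-reachability
            mask = rng.random((n, n)) < 0.2
            D[mask] = np.inf
            np.fill_diagonal(D, np.inf)
            D[0, :] = np.minimum(D[0, :], rng.random(n) * 10)  # root can reach
            np.fill_diagonal(D, np.inf)
            best, _ = _brute_force_arborescence(D, 0)
            if not np.isfinite(best):
                with pytest.raises(ValidationError):
                    min_arborescence(D, 0)
                continue
            _, total = min_arborescence(D, 0)
            assert total == pytest.approx(best, abs=1e-9), trial

    def test_unreachable_node_reported(self):
        D = np.full((3, 3), np.inf)
        D[0, 1] = 1.0
        with pytest.raises(ValidationError, match=r"\[2\]"):
            min_arborescence(D, 0)

    def test_planted_linear_lineage_recovered(self):
        """K=4 clusters along the gradient: the tree is the chain
        0 -> 1 -> 2 -> 3."""
        from carcinomap import STSimConfig, syndata, st_core

        ds = syndata.generate_st_dataset(
            STSimConfig(n_clusters=4, n_spots_per_cluster=150)
        )
        ds, _ = st_core.qc_filter(ds, 1, 1)
        ds = st_core.normalize_log(ds)
        traj = infer_trajectory(
            ds, ds.truth["cluster"].to_numpy(), root_cluster=0
        )
        assert [(p, c) for p, c, _ in traj.edges] == [(0, 1), (1, 2), (2, 3)]


class TestPipelineDeterminism:
    def test_same_inputs_same_trajectory(self, st_small):
        labels = st_small.truth["cluster"].to_numpy()
        t1 = infer_trajectory(st_small, labels, root_cluster=0)
        t2 = infer_trajectory(st_small, labels, root_cluster=0)
        np.testing.assert_array_equal(t1.pseudotime, t2.pseudotime)
        assert t1.edges == t2.edges
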
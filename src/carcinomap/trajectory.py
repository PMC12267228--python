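"""Spatial pseudotime and evolutionary-trajectory inference.

The procedure:

1. a diffusion operator (random-walk transition matrix) is built from the
   expression kNN graph with Gaussian-kernel affinities and density
   normalization;
2. diffusion pseudotime (DPT) of each spot is its Euclidean distance from a
   root spot in the eigenvalue-rescaled diffusion-map embedding
   ``psi_i * lambda_i / (1 - lambda_i)``, rescaled to [0, 1];
3. cluster-level connectivity is the observed inter-cluster edge count over
   its degree-preserving expectation (a PAGA-style abstraction);
4. the pseudo-space-time distance (PSTD) between cluster nodes is a convex
   combination ``alpha * d_expr + (1 - alpha) * d_spatial`` of min-max
   normalized expression- and spatial-centroid distances, directed by
   forbidding edges that run backwards in mean pseudotime;
5. the rooted directed minimum spanning tree (minimum arborescence,
   Chu-Liu/Edmonds) over the finite PSTD entries gives the lineage tree.

The root is always user-specified (a cluster id, optionally a spot id),
reflecting that trajectory direction is fixed by the biological process,
not inferred.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .datatypes import SpotDataset, ValidationError
from .st_core import KnnGraph, build_knn_graph, run_pca


# ---------------------------------------------------------------------------
# Diffusion operator and pseudotime
# ---------------------------------------------------------------------------

@dataclass
class DiffusionOperator:
    """Row-stochastic diffusion transition matrix with its top eigenpairs.

    ``nodes`` maps operator rows back to indices in the original graph
    (a proper subset when the graph was disconnected and the largest
    component was used).
    """

    transition: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns are right eigenvectors of `transition`
    nodes: np.ndarray
    n_components: int
    n_total: int = 0  # node count of the original graph


def _edge_adjacency(graph: KnnGraph) -> coo_matrix:
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    d = graph.distances
    return coo_matrix(
        (np.concatenate([d, d]), (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(graph.n_nodes, graph.n_nodes),
    )


def connect_components(graph: KnnGraph, points: np.ndarray) -> KnnGraph:
    """Bridge disconnected graph components with nearest cross pairs.

    Strongly separated clusters can fragment the expression kNN graph,
    which breaks random-walk pseudotime.  Per merge step, the two closest
    components are joined by their ``k`` shortest cross-component point
    pairs (matching the neighborhood density elsewhere in the graph, so
    the bridge is not an artificial one-edge bottleneck), until the graph
    is connected.  Bridge edges carry weight 0 in SNN terms and their true
    Euclidean length as distance.  A connected input is returned as is.
    """
    points = np.asarray(points, dtype=np.float64)
    adj = _edge_adjacency(graph).tocsr()
    n_comp, labels = connected_components(adj > 0, directed=False)
    if n_comp <= 1:
        return graph
    edges = [tuple(e) for e in graph.edges]
    dists = list(graph.distances)
    weights = list(graph.weights)
    labels = labels.copy()
    while n_comp > 1:
        best = None
        for a in range(n_comp):
            ia = np.flatnonzero(labels == a)
            for b in range(a + 1, n_comp):
                ib = np.flatnonzero(labels == b)
                d = np.linalg.norm(
                    points[ia][:, None, :] - points[ib][None, :, :], axis=-1
                )
                pos = np.unravel_index(np.argmin(d), d.shape)
                cand = (float(d[pos]), int(a), int(b), d, ia, ib)
                if best is None or cand[0] < best[0]:
                    best = cand
        _, a, b, d, ia, ib = best
        n_bridge = min(graph.k, d.size)
        flat = np.argsort(d, axis=None, kind="stable")[:n_bridge]
        for f in flat:
            i_pos, j_pos = np.unravel_index(f, d.shape)
            u, v = int(ia[i_pos]), int(ib[j_pos])
            edges.append((min(u, v), max(u, v)))
            dists.append(float(d[i_pos, j_pos]))
            weights.append(0.0)
        labels[labels == b] = a
        labels[labels > b] -= 1
        n_comp -= 1
    order = np.argsort([e[0] * graph.n_nodes + e[1] for e in edges])
    return KnnGraph(
        n_nodes=graph.n_nodes,
        edges=np.array(edges)[order],
        weights=np.array(weights)[order],
        distances=np.array(dists)[order],
        k=graph.k,
    )


def build_diffusion(graph: KnnGraph, n_components: int = 15) -> DiffusionOperator:
    """Gaussian-kernel diffusion operator on the kNN graph.

    Affinities use locally scaled bandwidths (each node's mean edge
    distance), are density-normalized, then row-normalized into a
    stochastic matrix.  Eigenpairs are computed through the symmetric
    conjugate matrix, with eigenvector signs fixed so each vector's
    largest-magnitude entry is positive.  A disconnected graph is reduced
    to its largest component with a warning.
    """
    adj = _edge_adjacency(graph).tocsr()
    n_comp, comp_labels = connected_components(adj > 0, directed=False)
    nodes = np.arange(graph.n_nodes)
    if n_comp > 1:
        sizes = np.bincount(comp_labels)
        keep = comp_labels == np.argmax(sizes)
        warnings.warn(
            f"graph has {n_comp} components; using largest "
            f"({int(keep.sum())}/{graph.n_nodes} nodes)",
            stacklevel=2,
        )
        nodes = np.flatnonzero(keep)
        adj = adj[np.ix_(nodes, nodes)]
    A = adj.toarray()
    n = A.shape[0]
    if n_components >= n:
        warnings.warn(
            f"n_components={n_components} >= n={n}; reduced to {n - 1}",
            stacklevel=2,
        )
        n_components = n - 1

    mask = A > 0
    # Local bandwidth: mean incident edge length (strictly positive by
    # construction except for duplicate points; floor avoids division by 0).
    with np.errstate(invalid="ignore"):
        sigma = np.where(
            mask.sum(1) > 0, A.sum(1) / np.maximum(mask.sum(1), 1), 1.0
        )
    sigma = np.maximum(sigma, 1e-12)
    # Per-edge bandwidth is floored at (d/2)^2 so no retained edge falls
    # below affinity exp(-4): the sparse graph already encodes locality,
    # and vanishing kernel tails on bottleneck (bridge) edges would push
    # eigenvalues arbitrarily close to 1 and destabilize pseudotime.
    K = np.zeros_like(A)
    bw = np.maximum(np.outer(sigma, sigma)[mask], (A[mask] ** 2) / 4.0)
    K[mask] = np.exp(-(A[mask] ** 2) / bw)
    np.fill_diagonal(K, 1.0)
    # Density normalization (alpha = 1) removes sampling-density bias.
    q = K.sum(1)
    K = K / np.outer(q, q)
    d = K.sum(1)
    M = K / d[:, None]

    # Eigendecomposition via the symmetric conjugate S = D^1/2 M D^-1/2.
    d_sqrt = np.sqrt(d)
    S = K / np.outer(d_sqrt, d_sqrt)
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1][: n_components]
    evals = evals[order]
    psi = evecs[:, order] / d_sqrt[:, None]
    # Normalize and fix signs.
    psi = psi / np.linalg.norm(psi, axis=0, keepdims=True)
    for c in range(psi.shape[1]):
        j = int(np.argmax(np.abs(psi[:, c])))
        if psi[j, c] < 0:
            psi[:, c] = -psi[:, c]
    return DiffusionOperator(
        transition=M,
        eigenvalues=evals,
        eigenvectors=psi,
        nodes=nodes,
        n_components=n_components,
        n_total=graph.n_nodes,
    )


def diffusion_pseudotime(op: DiffusionOperator, root_spot: int) -> np.ndarray:
    """DPT of every node relative to ``root_spot`` (an original graph index).

    Returns an array over the original graph's nodes, NaN for nodes outside
    the operator's component; values are rescaled to [0, 1] with the root
    at 0.
    """
    pos = np.flatnonzero(op.nodes == root_spot)
    if pos.size == 0:
        raise ValidationError(
            f"root spot {root_spot} is not in the diffusion operator's component"
        )
    root = int(pos[0])
    lam = op.eigenvalues
    if op.n_components >= 2 and lam[1] > 1 - 1e-10:
        raise ValidationError(
            "eigenvalue 1 has multiplicity > 1: the graph is disconnected; "
            "restrict to one connected component first"
        )
    keep = slice(1, None)  # drop the trivial constant eigenvector
    scale = lam[keep] / (1.0 - lam[keep])
    coords = op.eigenvectors[:, keep] * scale[None, :]
    dist = np.linalg.norm(coords - coords[root], axis=1)
    if dist.max() > 0:
        dist = dist / dist.max()
    n_total = op.n_total if op.n_total else int(op.nodes.max()) + 1
    tau = np.full(n_total, np.nan)
    tau[op.nodes] = dist
    return tau


# ---------------------------------------------------------------------------
# Cluster-level abstraction
# ---------------------------------------------------------------------------

def cluster_connectivity(graph: KnnGraph, labels: np.ndarray) -> np.ndarray:
    """Observed / expected inter-cluster edge counts (degree-preserving).

    Entry (a, b) is the number of edges between clusters a and b divided by
    its expectation ``deg_a * deg_b / (2m)`` under random edge placement
    with the observed degree totals.  Symmetric, zero diagonal, zero for
    unlinked pairs.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValidationError("connectivity needs at least 2 clusters")
    index = {c: i for i, c in enumerate(uniq)}
    K = uniq.size
    m = graph.edges.shape[0]
    deg = np.bincount(graph.edges.ravel(), minlength=graph.n_nodes)
    deg_cluster = np.zeros(K)
    for c, i in index.items():
        deg_cluster[i] = deg[labels == c].sum()
    observed = np.zeros((K, K))
    for a, b in graph.edges:
        ca, cb = index[labels[a]], index[labels[b]]
        if ca != cb:
            observed[ca, cb] += 1
            observed[cb, ca] += 1
    expected = np.outer(deg_cluster, deg_cluster) / max(2 * m, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        conn = np.where(expected > 0, observed / expected, 0.0)
    np.fill_diagonal(conn, 0.0)
    return conn


@dataclass
class ClusterNodes:
    """Per-cluster summaries used as trajectory tree nodes."""

    cluster_ids: np.ndarray
    expr_centroid: np.ndarray     # (K, d) in the embedding / PC space
    spatial_centroid: np.ndarray  # (K, 2) in pixel coordinates
    mean_tau: np.ndarray
    sizes: np.ndarray


def make_cluster_nodes(
    labels: np.ndarray,
    expr_coords: np.ndarray,
    spatial_coords: np.ndarray,
    tau: np.ndarray,
) -> ClusterNodes:
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    expr_c, spat_c, mtau, sizes = [], [], [], []
    for c in uniq:
        mask = labels == c
        expr_c.append(expr_coords[mask].mean(axis=0))
        spat_c.append(spatial_coords[mask].mean(axis=0))
        mtau.append(np.nanmean(tau[mask]))
        sizes.append(int(mask.sum()))
    return ClusterNodes(
        cluster_ids=uniq,
        expr_centroid=np.array(expr_c),
        spatial_centroid=np.array(spat_c),
        mean_tau=np.array(mtau),
        sizes=np.array(sizes),
    )


def _minmax_offdiag(D: np.ndarray, what: str) -> np.ndarray:
    off = ~np.eye(D.shape[0], dtype=bool)
    vals = D[off]
    lo, hi = vals.min(), vals.max()
    if hi - lo <= 0:
        warnings.warn(
            f"degenerate {what} distances (all pairs equal); term set to 0",
            stacklevel=3,
        )
        return np.zeros_like(D)
    out = (D - lo) / (hi - lo)
    np.fill_diagonal(out, 0.0)
    return out


def pstd(nodes: ClusterNodes, alpha: float = 0.5) -> np.ndarray:
    """Directed pseudo-space-time distance matrix between cluster nodes.

    ``d(i -> j) = alpha * d_expr + (1 - alpha) * d_spatial`` with each term
    min-max normalized over off-diagonal pairs; edges running backwards in
    mean pseudotime (``mean_tau[j] < mean_tau[i]``) are forbidden
    (+infinity), as is the diagonal.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValidationError("alpha must lie in [0, 1]")
    K = nodes.cluster_ids.size
    d_expr = np.linalg.norm(
        nodes.expr_centroid[:, None, :] - nodes.expr_centroid[None, :, :], axis=-1
    )
    d_spat = np.linalg.norm(
        nodes.spatial_centroid[:, None, :] - nodes.spatial_centroid[None, :, :],
        axis=-1,
    )
    D = alpha * _minmax_offdiag(d_expr, "expression") + (1 - alpha) * _minmax_offdiag(
        d_spat, "spatial"
    )
    tau = nodes.mean_tau
    back = tau[None, :] < tau[:, None]  # j earlier than i
    D = np.where(back, np.inf, D)
    np.fill_diagonal(D, np.inf)
    return D


# ---------------------------------------------------------------------------
# Minimum arborescence
# ---------------------------------------------------------------------------

def min_arborescence(
    dist: np.ndarray, root: int
) -> Tuple[list, float]:
    """Minimum-weight spanning arborescence rooted at ``root``.

    ``dist[i, j]`` is the directed edge weight i -> j (+inf = forbidden).
    Uses the Chu-Liu/Edmonds algorithm.  Returns ``(edges, total_weight)``
    with edges as (parent, child, weight) triples.
    """
    dist = np.asarray(dist, dtype=np.float64)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValidationError("distance matrix must be square")
    if not (0 <= root < n):
        raise ValidationError(f"root {root} out of range")
    finite = np.isfinite(dist)
    # Reachability check from root over finite edges.
    reach = {root}
    frontier = [root]
    while frontier:
        i = frontier.pop()
        for j in np.flatnonzero(finite[i]):
            if j not in reach:
                reach.add(int(j))
                frontier.append(int(j))
    missing = sorted(set(range(n)) - reach)
    if missing:
        raise ValidationError(
            f"nodes {missing} are not reachable from root {root} via finite edges"
        )
    G = nx.DiGraph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in np.flatnonzero(finite[i]):
            if j != root:  # the root never receives an edge
                G.add_edge(i, int(j), weight=float(dist[i, j]))
    try:
        arb = nx.minimum_spanning_arborescence(G, attr="weight",
                                               preserve_attrs=True)
    except nx.NetworkXException as exc:
        raise ValidationError(f"no spanning arborescence exists: {exc}") from exc
    edges = sorted(
        (int(u), int(v), float(d["weight"])) for u, v, d in arb.edges(data=True)
    )
    if len(edges) != n - 1:
        raise ValidationError("no spanning arborescence exists")
    return edges, float(sum(w for _, _, w in edges))


# ---------------------------------------------------------------------------
# End-to-end trajectory
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryGraph:
    """Per-spot pseudotime plus the rooted directed tree over clusters."""

    root_cluster: int
    pseudotime: np.ndarray
    nodes: ClusterNodes
    edges: list  # (parent_cluster, child_cluster, weight)
    alpha: float
    connectivity: Optional[np.ndarray] = None

    def parent_of(self) -> dict:
        return {child: parent for parent, child, _ in self.edges}

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.edges, columns=["parent", "child", "pstd_weight"]
        )

    def to_dot(self) -> str:
        lines = ["digraph trajectory {"]
        for c, size in zip(self.nodes.cluster_ids, self.nodes.sizes):
            shape = "doublecircle" if c == self.root_cluster else "circle"
            lines.append(f'  {c} [label="c{c} (n={size})", shape={shape}];')
        for p, ch, w in self.edges:
            lines.append(f'  {p} -> {ch} [label="{w:.3f}"];')
        lines.append("}")
        return "\n".join(lines)


def infer_trajectory(
    ds: SpotDataset,
    labels: np.ndarray,
    root_cluster: int,
    layer: str = "lognorm",
    n_pcs: int = 20,
    k: int = 15,
    n_diffusion_components: int = 15,
    alpha: float = 0.5,
    root_spot: Optional[int] = None,
) -> TrajectoryGraph:
    """Full spatial-trajectory inference on a clustered dataset.

    PCA on the normalized layer -> kNN graph -> diffusion pseudotime from a
    root spot (by default the root cluster's spot closest to its expression
    centroid) -> cluster nodes -> PSTD -> minimum arborescence.
    """
    labels = np.asarray(labels)
    if root_cluster not in np.unique(labels):
        raise ValidationError(f"root cluster {root_cluster} not present")
    if layer not in ds.layers:
        raise ValidationError(f"layer '{layer}' missing; run normalize_log")
    X = ds.layers[layer].T  # spots x genes
    pca = run_pca(X, n_pcs=min(n_pcs, min(X.shape)))
    graph = build_knn_graph(pca.scores, k=k)
    graph = connect_components(graph, pca.scores)
    op = build_diffusion(graph, n_components=n_diffusion_components)

    if root_spot is None:
        in_root = np.flatnonzero(labels == root_cluster)
        centroid = pca.scores[in_root].mean(axis=0)
        root_spot = int(in_root[np.argmin(
            np.linalg.norm(pca.scores[in_root] - centroid, axis=1)
        )])
    tau = diffusion_pseudotime(op, root_spot)

    spatial = ds.coords[["pixel_x", "pixel_y"]].to_numpy(dtype=float)
    nodes = make_cluster_nodes(labels, pca.scores, spatial, tau)
    D = pstd(nodes, alpha=alpha)
    root_idx = int(np.flatnonzero(nodes.cluster_ids == root_cluster)[0])
    edges_idx, _ = min_arborescence(D, root_idx)
    edges = [
        (int(nodes.cluster_ids[p]), int(nodes.cluster_ids[c]), w)
        for p, c, w in edges_idx
    ]
    conn = cluster_connectivity(graph, labels) if np.unique(labels).size > 1 else None
    return TrajectoryGraph(
        root_cluster=int(root_cluster),
        pseudotime=tau,
        nodes=nodes,
        edges=edges,
        alpha=alpha,
        connectivity=conn,
    )
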
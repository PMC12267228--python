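"""Spot-level preprocessing, embedding, clustering and marker detection.

The stage order mirrors a standard spatial-transcriptomics workflow:
QC filtering of damaged/empty spots, library-size log-normalization,
highly-variable-gene selection, PCA, optional batch-centroid alignment,
a shared-nearest-neighbor kNN graph, Leiden community detection, a 2D
embedding for visualization, and per-cluster marker detection with a
bimodal (zero-inflation + positive component) likelihood-ratio test.

Normalization is log1p counts-per-10k: a deliberately simple
variance-stabilization whose downstream contracts (clustering, markers,
trajectories) do not depend on the specific transform.  Batch correction is
per-batch centroid alignment in PC space, sufficient for additive batch
offsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from ._random import child_int
from .datatypes import SpotDataset, ValidationError

DEFAULT_LAYER = "lognorm"
#: Leiden resolution defaults: 0.1 for image-tile clustering (empirically
#: set for coarse sub-regions), 1.0 for expression data.
DEFAULT_RESOLUTION_TILES = 0.1
DEFAULT_RESOLUTION_EXPR = 1.0


class EmptyDatasetError(ValidationError):
    """All spots were removed by filtering."""


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------

def qc_metrics(ds: SpotDataset) -> pd.DataFrame:
    """Per-spot QC table: UMI total and number of detected genes."""
    return pd.DataFrame(
        {
            "umi_total": ds.counts.sum(axis=0),
            "n_genes_detected": (ds.counts > 0).sum(axis=0),
        },
        index=pd.Index(ds.spot_ids, name="barcode"),
    )


def qc_filter(
    ds: SpotDataset, min_genes: int = 0, min_umi: int = 0
) -> Tuple[SpotDataset, pd.DataFrame]:
    """Remove damaged or empty spots.

    A spot is kept when it detects at least ``min_genes`` genes and its UMI
    total is at least ``min_umi``.  Returns the filtered dataset and the
    QC table of the *input* spots with a ``kept`` column.
    """
    if min_genes < 0 or min_umi < 0:
        raise ValidationError("QC thresholds must be >= 0")
    metrics = qc_metrics(ds)
    keep = (
        (metrics["n_genes_detected"].to_numpy() >= min_genes)
        & (metrics["umi_total"].to_numpy() >= min_umi)
    )
    metrics["kept"] = keep
    if not keep.any():
        raise EmptyDatasetError(
            "QC filtering removed every spot "
            f"(min_genes={min_genes}, min_umi={min_umi})"
        )
    return ds.subset_spots(keep), metrics


def normalize_log(
    ds: SpotDataset, scale_factor: float = 1e4, layer: str = DEFAULT_LAYER
) -> SpotDataset:
    """Store ``log(1 + count / spot_total * scale_factor)`` as a named layer."""
    totals = ds.counts.sum(axis=0).astype(np.float64)
    if np.any(totals == 0):
        bad = ds.spot_ids[totals == 0][:5]
        raise ValidationError(
            f"zero-total spots present (e.g. {list(bad)}); run qc_filter first"
        )
    norm = np.log1p(ds.counts / totals[None, :] * scale_factor)
    ds.layers[layer] = norm
    return ds


def select_hvg(
    ds: SpotDataset, n_top: int, layer: str = DEFAULT_LAYER
) -> np.ndarray:
    """Indices of the ``n_top`` genes with highest normalized-value variance.

    Ties are broken by gene order (lower index wins).
    """
    if n_top <= 0:
        raise ValidationError("n_top must be positive")
    if layer not in ds.layers:
        raise ValidationError(f"layer '{layer}' missing; run normalize_log")
    n_top = min(n_top, ds.n_genes)
    var = ds.layers[layer].var(axis=1, ddof=1)
    order = np.lexsort((np.arange(ds.n_genes), -var))
    return np.sort(order[:n_top])


# ---------------------------------------------------------------------------
# PCA and batch correction
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: np.ndarray          # (n_obs, n_pcs)
    components: np.ndarray      # (n_pcs, n_vars), orthonormal rows
    explained_variance: np.ndarray

    @property
    def n_pcs(self) -> int:
        return self.scores.shape[1]


def run_pca(matrix: np.ndarray, n_pcs: int, center: bool = True) -> PCAResult:
    """PCA via SVD with a deterministic sign convention.

    Each component's largest-magnitude loading (first index on ties) is made
    positive.  If ``n_pcs`` exceeds the numerical rank, the available
    components are returned with a warning.
    """
    X = np.asarray(matrix, dtype=np.float64)
    if n_pcs <= 0:
        raise ValidationError("n_pcs must be positive")
    if n_pcs > min(X.shape):
        raise ValidationError(
            f"n_pcs={n_pcs} exceeds min(matrix dims)={min(X.shape)}"
        )
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    tol = S[0] * max(X.shape) * np.finfo(np.float64).eps if S.size else 0.0
    rank = int(np.sum(S > tol))
    if n_pcs > rank:
        warnings.warn(
            f"requested {n_pcs} PCs but matrix rank is {rank}; returning {rank}",
            stacklevel=2,
        )
        n_pcs = max(rank, 1)
    U, S, Vt = U[:, :n_pcs], S[:n_pcs], Vt[:n_pcs]
    # Sign convention: largest-|loading| entry of each component positive.
    flip = np.array(
        [np.sign(row[np.argmax(np.abs(row))]) or 1.0 for row in Vt]
    )
    Vt = Vt * flip[:, None]
    scores = U * S[None, :] * flip[None, :]
    explained = S**2 / max(X.shape[0] - 1, 1)
    return PCAResult(scores=scores, components=Vt, explained_variance=explained)


def correct_batch(scores: np.ndarray, batch_labels: Sequence) -> np.ndarray:
    """Align per-batch centroids in PC space, preserving the global centroid.

    A pure translation per batch: within-batch geometry is untouched, and a
    single batch is returned unchanged.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(batch_labels)
    if len(labels) != scores.shape[0]:
        raise ValidationError("one batch label per observation required")
    uniq = np.unique(labels)
    if uniq.size == 0:
        raise ValidationError("at least one batch required")
    if uniq.size == 1:
        return scores.copy()
    global_centroid = scores.mean(axis=0)
    out = scores.copy()
    for b in uniq:
        mask = labels == b
        out[mask] += global_centroid - scores[mask].mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# kNN graph and clustering
# ---------------------------------------------------------------------------

@dataclass
class KnnGraph:
    """Undirected kNN graph with shared-nearest-neighbor edge weights."""

    n_nodes: int
    edges: np.ndarray       # (m, 2) with i < j
    weights: np.ndarray     # SNN Jaccard similarity in [0, 1]
    distances: np.ndarray   # Euclidean distance per edge
    k: int


def build_knn_graph(
    scores: np.ndarray, k: int = 15, metric: str = "euclidean"
) -> KnnGraph:
    """kNN graph symmetrized by union, weighted by shared-neighbor Jaccard.

    Each point is linked to its ``k`` nearest neighbors (ties resolved by
    index via a stable sort); the edge set is the union over directions.
    The weight of edge (i, j) is the Jaccard similarity of the two
    neighborhoods, each including the point itself.
    """
    X = np.asarray(scores, dtype=np.float64)
    n = X.shape[0]
    if k <= 0:
        raise ValidationError("k must be positive")
    if k >= n:
        raise ValidationError(f"k={k} must be < n_points={n}")
    nn = NearestNeighbors(n_neighbors=k + 1, metric=metric, algorithm="brute")
    nn.fit(X)
    dist, idx = nn.kneighbors(X)
    # Drop self (guaranteed nearest with distance 0 after stable sort on
    # equal distances is not guaranteed by sklearn, so remove explicitly).
    neigh = np.empty((n, k), dtype=int)
    neigh_d = np.empty((n, k), dtype=float)
    for i in range(n):
        row = [(d, j) for d, j in zip(dist[i], idx[i]) if j != i]
        row.sort()
        row = row[:k]
        neigh[i] = [j for _, j in row]
        neigh_d[i] = [d for d, _ in row]

    neighbor_sets = [set(neigh[i]) | {i} for i in range(n)]
    edge_map: dict = {}
    for i in range(n):
        for j_pos, j in enumerate(neigh[i]):
            a, b = (i, j) if i < j else (j, i)
            if (a, b) not in edge_map:
                edge_map[(a, b)] = neigh_d[i][j_pos]
    edges = np.array(sorted(edge_map), dtype=int).reshape(-1, 2)
    distances = np.array([edge_map[tuple(e)] for e in edges])
    weights = np.array(
        [
            len(neighbor_sets[a] & neighbor_sets[b])
            / len(neighbor_sets[a] | neighbor_sets[b])
            for a, b in edges
        ]
    )
    return KnnGraph(
        n_nodes=n, edges=edges, weights=weights, distances=distances, k=k
    )


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    resolution: float
    k_neighbors: int

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


def canonicalize_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters: 0 = largest, ties by smallest member index."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    keyed = sorted(
        uniq,
        key=lambda c: (-(labels == c).sum(), int(np.flatnonzero(labels == c)[0])),
    )
    remap = {old: new for new, old in enumerate(keyed)}
    return np.array([remap[c] for c in labels], dtype=int)


def cluster_graph(
    graph: KnnGraph, resolution: float = DEFAULT_RESOLUTION_EXPR, seed: int = 0
) -> ClusterAssignment:
    """Leiden community detection with a resolution-parameterized modularity."""
    import igraph
    import leidenalg

    if graph.n_nodes == 0:
        raise ValidationError("cannot cluster an empty graph")
    g = igraph.Graph(n=graph.n_nodes, edges=[tuple(e) for e in graph.edges])
    partition = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=list(graph.weights),
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels = canonicalize_labels(np.array(partition.membership))
    return ClusterAssignment(labels=labels, resolution=resolution,
                             k_neighbors=graph.k)


def embed_2d(
    scores: np.ndarray, method: str = "umap", seed: int = 0
) -> np.ndarray:
    """2D embedding (UMAP or t-SNE), deterministic given the seed."""
    X = np.asarray(scores, dtype=np.float64)
    n = X.shape[0]
    if n < 3:
        raise ValidationError("at least 3 points required for embedding")
    if method == "umap":
        import umap

        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=min(15, n - 1),
            min_dist=0.1,
            random_state=child_int(seed, "umap"),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.asarray(reducer.fit_transform(X), dtype=np.float64)
    if method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = min(30.0, max((n - 1) / 3.0, 2.0))
        tsne = TSNE(
            n_components=2,
            perplexity=perplexity,
            init="pca",
            random_state=child_int(seed, "tsne"),
        )
        return np.asarray(tsne.fit_transform(X), dtype=np.float64)
    raise ValidationError(f"unknown embedding method '{method}'")


# ---------------------------------------------------------------------------
# Bimod marker test
# ---------------------------------------------------------------------------

_SIGMA_FLOOR = 1e-8


def _zin_loglik(x: np.ndarray, p_det: float, mu: float, sigma: float) -> float:
    """Log-likelihood of the zero-inflated normal (bimodal) model.

    Zeros occur with probability ``1 - p_det``; positive values are
    Normal(mu, sigma).
    """
    eps = 1e-300
    pos = x > 0
    k = int(pos.sum())
    n = x.size
    ll = (n - k) * np.log(max(1.0 - p_det, eps)) + k * np.log(max(p_det, eps))
    if k:
        ll += float(stats.norm.logpdf(x[pos], mu, sigma).sum())
    return ll


def bimod_lrt(x_a: np.ndarray, x_b: np.ndarray) -> Tuple[float, float]:
    """Likelihood-ratio test of group difference under the bimodal model.

    H0: shared detection rate and positive mean; H1: group-specific
    detection rates and positive means; the positive-component SD is shared
    and re-estimated under each hypothesis.  2 * delta-log-likelihood is
    referred to chi-square with 2 df.  Returns ``(statistic, p)``.
    """
    x_a = np.asarray(x_a, dtype=np.float64)
    x_b = np.asarray(x_b, dtype=np.float64)
    pooled = np.concatenate([x_a, x_b])
    pos = pooled[pooled > 0]

    def _sigma(values: np.ndarray, means: np.ndarray) -> float:
        if values.size == 0:
            return _SIGMA_FLOOR
        return max(float(np.sqrt(np.mean((values - means) ** 2))), _SIGMA_FLOOR)

    # H0 fit
    p0 = float((pooled > 0).mean())
    mu0 = float(pos.mean()) if pos.size else 0.0
    s0 = _sigma(pos, np.full(pos.size, mu0))
    ll0 = _zin_loglik(x_a, p0, mu0, s0) + _zin_loglik(x_b, p0, mu0, s0)

    # H1 fit (shared sigma from within-group residuals)
    res, mus, ps = [], [], []
    for x in (x_a, x_b):
        xp = x[x > 0]
        mu = float(xp.mean()) if xp.size else 0.0
        mus.append(mu)
        ps.append(float((x > 0).mean()))
        res.append(xp - mu)
    resid = np.concatenate(res) if res else np.array([])
    s1 = _sigma(resid, np.zeros(resid.size))
    ll1 = _zin_loglik(x_a, ps[0], mus[0], s1) + _zin_loglik(x_b, ps[1], mus[1], s1)

    stat = max(2.0 * (ll1 - ll0), 0.0)
    p = float(stats.chi2.sf(stat, df=2)) if stat > 0 else 1.0
    return stat, p


def find_markers_bimod(
    ds: SpotDataset,
    labels: np.ndarray,
    layer: str = DEFAULT_LAYER,
    min_cluster_size: int = 3,
) -> pd.DataFrame:
    """One-vs-rest bimod LRT for every gene and cluster.

    Returns a table with the LRT statistic, raw and BH-adjusted p (within
    each cluster contrast), linear fold change on de-logged means, log2 fold
    change, detection fractions, and an ``is_marker`` flag for genes
    upregulated in their cluster.
    """
    from .diffexpr import bh_adjust, fold_change_from_lognorm

    if layer not in ds.layers:
        raise ValidationError(f"layer '{layer}' missing; run normalize_log")
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValidationError("marker detection needs at least 2 clusters")
    X = ds.layers[layer]
    records = []
    for c in uniq:
        in_c = labels == c
        if in_c.sum() < min_cluster_size:
            warnings.warn(
                f"cluster {c} has fewer than {min_cluster_size} spots; skipped",
                stacklevel=2,
            )
            continue
        Xin, Xout = X[:, in_c], X[:, ~in_c]
        fc = fold_change_from_lognorm(Xin, Xout)
        pct_in = (Xin > 0).mean(axis=1)
        pct_out = (Xout > 0).mean(axis=1)
        stats_p = [bimod_lrt(Xin[g], Xout[g]) for g in range(ds.n_genes)]
        stat = np.array([s for s, _ in stats_p])
        pval = np.array([p for _, p in stats_p])
        qval = bh_adjust(pval)
        for g in range(ds.n_genes):
            records.append(
                (
                    c,
                    ds.gene_ids[g],
                    stat[g],
                    pval[g],
                    qval[g],
                    fc[g],
                    np.log2(fc[g]) if fc[g] > 0 else -np.inf,
                    pct_in[g],
                    pct_out[g],
                )
            )
    table = pd.DataFrame(
        records,
        columns=[
            "cluster", "gene", "lrt_stat", "p", "q",
            "fold_change", "log2_fc", "pct_in", "pct_out",
        ],
    )
    table["is_marker"] = (table["fold_change"] > 1) & (table["p"] < 0.05)
    return table


def top_markers(table: pd.DataFrame, cluster, n: int = 50) -> pd.DataFrame:
    """Top-n upregulated markers of one cluster, ordered by (p, -fold_change)."""
    sub = table[(table["cluster"] == cluster) & (table["fold_change"] > 1)]
    return sub.sort_values(["p", "fold_change"], ascending=[True, False]).head(n)
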
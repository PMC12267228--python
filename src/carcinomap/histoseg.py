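"""Unsupervised whole-slide-image sub-region segmentation.

Pipeline: Otsu tissue masking -> sliding-window tiling (512 px window,
128 px stride at 20x by default) -> per-tile features through a pluggable
extractor -> variance-based feature selection (top 256) -> PCA -> kNN
graph -> Leiden communities (resolution 0.1) -> per-pixel majority-vote
label map.

The default extractor is a handcrafted 64-dimensional descriptor
(intensity histogram, channel moments, gradient-magnitude statistics and a
local-binary-pattern histogram); features from any external model can be
supplied instead as a (tiles x D) table keyed by tile coordinates.

Coordinates are 0-based, top-left origin; tiles are half-open boxes
``[x, x + w) x [y, y + h)``.  Clustering is per slide: labels from
different slides are not comparable.
"""

from __future__ import annotations

import abc
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage.feature import local_binary_pattern
from skimage.filters import sobel

from .datatypes import TileSet, ValidationError
from .st_core import (
    DEFAULT_RESOLUTION_TILES,
    build_knn_graph,
    canonicalize_labels,
    cluster_graph,
    run_pca,
)

DEFAULT_WINDOW = 512
DEFAULT_STRIDE = 128
DEFAULT_TOP_FEATURES = 256


# ---------------------------------------------------------------------------
# Tissue masking
# ---------------------------------------------------------------------------

def otsu_threshold(image: np.ndarray) -> int:
    """Otsu's threshold on the 256-bin histogram of an 8-bit image.

    Returns the threshold ``t`` maximizing between-class variance of the
    split ``value <= t`` vs ``value > t``; ties resolve to the lowest ``t``.
    A constant image yields its own value with a warning.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValidationError("empty image")
    vals = np.clip(np.rint(img), 0, 255).astype(np.int64).ravel()
    hist = np.bincount(vals, minlength=256).astype(np.float64)
    total = hist.sum()
    if np.count_nonzero(hist) == 1:
        level = int(np.flatnonzero(hist)[0])
        warnings.warn(
            f"constant image (value {level}); Otsu threshold is degenerate",
            stacklevel=2,
        )
        return level
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)
    m0 = np.cumsum(hist * levels)
    mu_total = m0[-1]
    best_t, best_var = 0, -1.0
    for t in range(256):
        n0, n1 = w0[t], total - w0[t]
        if n0 == 0 or n1 == 0:
            continue
        mu0 = m0[t] / n0
        mu1 = (mu_total - m0[t]) / n1
        var = n0 * n1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return int(best_t)


def tissue_mask(image: np.ndarray, dark_is_tissue: bool = True) -> np.ndarray:
    """Boolean tissue mask by Otsu thresholding (H&E tissue is dark)."""
    img = np.asarray(image)
    if img.ndim == 3:
        img = img.mean(axis=2)
    t = otsu_threshold(img)
    return (img <= t) if dark_is_tissue else (img > t)


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------

def tile_grid(
    width: int, height: int, window: int = DEFAULT_WINDOW,
    stride: int = DEFAULT_STRIDE,
) -> np.ndarray:
    """Sliding-window tile coordinates, row-major.

    Positions are 0, stride, 2*stride, ... with the tile fully inside the
    image; per-axis count is ``floor((dim - window) / stride) + 1``.
    Returns an (n, 4) array of (x, y, w, h).
    """
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    if window < 1:
        raise ValidationError("window must be >= 1")
    if window > width or window > height:
        warnings.warn(
            f"window {window} exceeds image dims ({width}x{height}); no tiles",
            stacklevel=2,
        )
        return np.zeros((0, 4), dtype=int)
    xs = np.arange(0, width - window + 1, stride)
    ys = np.arange(0, height - window + 1, stride)
    coords = [(x, y) for y in ys for x in xs]
    out = np.array(
        [(x, y, window, window) for x, y in coords], dtype=int
    )
    return out


def filter_tissue_tiles(
    tiles: np.ndarray, mask: np.ndarray, min_fg_fraction: float = 0.5
) -> np.ndarray:
    """Keep tiles whose foreground fraction in ``mask`` is >= the minimum.

    Returns the kept subset of tile rows (same (x, y, w, h) layout).
    """
    tiles = np.asarray(tiles)
    mask = np.asarray(mask, dtype=bool)
    kept = []
    for x, y, w, h in tiles:
        patch = mask[y:y + h, x:x + w]
        if patch.size and patch.mean() >= min_fg_fraction:
            kept.append((x, y, w, h))
    return np.array(kept, dtype=int).reshape(-1, 4)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

class FeatureExtractor(abc.ABC):
    """Contract for per-tile feature extraction.

    Implementations must be deterministic and return a fixed-length vector
    for every tile image.
    """

    name: str = "abstract"
    dimension: int = 0

    @abc.abstractmethod
    def extract(self, tile_image: np.ndarray) -> np.ndarray:
        """Feature vector of length ``dimension`` for one tile image."""


class HandcraftedExtractor(FeatureExtractor):
    """64-dimensional handcrafted texture/intensity descriptor.

    Components: 16-bin normalized intensity histogram; per-channel mean and
    variance (6, grayscale channels replicated); 14-bin gradient-magnitude
    histogram plus gradient mean and variance; 26-bin uniform
    local-binary-pattern histogram (P=24, R=3).
    """

    name = "handcrafted64"
    dimension = 64
    _LBP_P, _LBP_R = 24, 3

    def extract(self, tile_image: np.ndarray) -> np.ndarray:
        img = np.asarray(tile_image, dtype=np.float64)
        if img.ndim == 2:
            channels = [img, img, img]
            gray = img
        else:
            channels = [img[..., c] for c in range(3)]
            gray = img[..., :3].mean(axis=2)
        gray01 = gray / 255.0

        hist, _ = np.histogram(gray, bins=16, range=(0, 255))
        hist = hist / max(hist.sum(), 1)

        moments = []
        for ch in channels:
            moments.extend([ch.mean() / 255.0, ch.var() / (255.0**2)])

        grad = sobel(gray01)
        ghist, _ = np.histogram(grad, bins=14, range=(0, 1))
        ghist = ghist / max(ghist.sum(), 1)
        gstats = [grad.mean(), grad.var()]

        lbp = local_binary_pattern(
            gray.astype(np.uint8), self._LBP_P, self._LBP_R, method="uniform"
        )
        lhist, _ = np.histogram(
            lbp, bins=self._LBP_P + 2, range=(0, self._LBP_P + 2)
        )
        lhist = lhist / max(lhist.sum(), 1)

        vec = np.concatenate([hist, moments, ghist, gstats, lhist])
        assert vec.size == self.dimension
        return vec


class FileFeatureLoader(FeatureExtractor):
    """Features precomputed by an external model, keyed by tile coordinates.

    Expects a table with columns x, y and feature columns; ``extract`` is
    unavailable (use :meth:`lookup`).
    """

    name = "file"

    def __init__(self, table: pd.DataFrame):
        feat_cols = [c for c in table.columns if c not in ("slide_id", "x", "y", "w", "h")]
        self._index = {
            (int(r.x), int(r.y)): i for i, r in enumerate(table.itertuples())
        }
        self._features = table[feat_cols].to_numpy(dtype=np.float64)
        self.dimension = self._features.shape[1]

    @classmethod
    def from_csv(cls, path) -> "FileFeatureLoader":
        return cls(pd.read_csv(path))

    def extract(self, tile_image: np.ndarray) -> np.ndarray:
        raise NotImplementedError(
            "FileFeatureLoader serves precomputed features; use lookup(tiles)"
        )

    def lookup(self, tiles: np.ndarray) -> np.ndarray:
        rows = []
        for x, y, _, _ in np.asarray(tiles):
            key = (int(x), int(y))
            if key not in self._index:
                raise ValidationError(f"no stored features for tile at {key}")
            rows.append(self._features[self._index[key]])
        return np.array(rows)


def extract_tile_features(
    image: np.ndarray, tiles: np.ndarray, extractor: Optional[FeatureExtractor] = None
) -> np.ndarray:
    """Apply an extractor to every tile of an image; (tiles x D) matrix."""
    extractor = extractor or HandcraftedExtractor()
    feats = [
        extractor.extract(image[y:y + h, x:x + w])
        for x, y, w, h in np.asarray(tiles)
    ]
    return np.array(feats, dtype=np.float64).reshape(len(feats), -1)


# ---------------------------------------------------------------------------
# Feature selection and clustering
# ---------------------------------------------------------------------------

def select_top_variance(features: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k highest-variance columns, in original column order."""
    X = np.asarray(features, dtype=np.float64)
    if k <= 0:
        raise ValidationError("k must be positive")
    if k > X.shape[1]:
        raise ValidationError(f"k={k} exceeds feature count {X.shape[1]}")
    var = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    order = np.lexsort((np.arange(X.shape[1]), -var))
    return np.sort(order[:k])


def cluster_tiles(
    features: np.ndarray,
    n_pcs: int = 32,
    resolution: float = DEFAULT_RESOLUTION_TILES,
    seed: int = 0,
    k_neighbors: int = 15,
) -> np.ndarray:
    """PCA -> kNN graph -> Leiden labels for a tile feature matrix."""
    X = np.asarray(features, dtype=np.float64)
    n = X.shape[0]
    if n == 0:
        raise ValidationError("no tiles to cluster")
    if n == 1:
        return np.zeros(1, dtype=int)
    # Standardize columns so heterogeneous feature scales do not dominate.
    sd = X.std(axis=0, ddof=0)
    Xs = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    n_pcs = min(n_pcs, min(Xs.shape) - 1) or 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pca = run_pca(Xs, n_pcs=n_pcs)
    graph = build_knn_graph(pca.scores, k=min(k_neighbors, n - 1))
    assignment = cluster_graph(graph, resolution=resolution, seed=seed)
    return canonicalize_labels(assignment.labels)


# ---------------------------------------------------------------------------
# Label map rendering
# ---------------------------------------------------------------------------

def _footprint_slices(
    x: int, y: int, w: int, h: int, downsample: int, out_h: int, out_w: int
) -> Tuple[slice, slice]:
    x0 = x // downsample
    y0 = y // downsample
    x1 = min(-(-(x + w) // downsample), out_w)
    y1 = min(-(-(y + h) // downsample), out_h)
    return slice(y0, y1), slice(x0, x1)


def render_label_map(
    tiles: np.ndarray,
    labels: np.ndarray,
    slide_shape: Tuple[int, int],
    downsample: int = 1,
) -> np.ndarray:
    """Per-pixel majority-vote label image.

    Each output pixel takes the most frequent label among tiles covering
    it (overlap is expected when stride < window); ties go to the smallest
    label id; pixels covered by no tile are -1.  ``slide_shape`` is
    (height, width) at level 0.
    """
    tiles = np.asarray(tiles)
    labels = np.asarray(labels)
    H = -(-slide_shape[0] // downsample)
    W = -(-slide_shape[1] // downsample)
    uniq = np.unique(labels) if labels.size else np.array([], dtype=int)
    votes = np.zeros((uniq.size, H, W), dtype=np.int32)
    for (x, y, w, h), lab in zip(tiles, labels):
        li = int(np.searchsorted(uniq, lab))
        ys, xs = _footprint_slices(x, y, w, h, downsample, H, W)
        votes[li, ys, xs] += 1
    out = np.full((H, W), -1, dtype=int)
    if uniq.size:
        covered = votes.sum(axis=0) > 0
        # argmax returns the first (smallest label) index on ties
        winner = uniq[np.argmax(votes, axis=0)]
        out[covered] = winner[covered]
    return out


# ---------------------------------------------------------------------------
# End-to-end segmentation of one slide
# ---------------------------------------------------------------------------

@dataclass
class SlideSegmentation:
    tileset: TileSet
    selected_features: np.ndarray
    label_map: np.ndarray
    threshold: int


def segment_slide(
    image: np.ndarray,
    slide_id: str = "slide",
    window: int = DEFAULT_WINDOW,
    stride: int = DEFAULT_STRIDE,
    min_fg_fraction: float = 0.5,
    top_features: int = DEFAULT_TOP_FEATURES,
    n_pcs: int = 32,
    resolution: float = DEFAULT_RESOLUTION_TILES,
    seed: int = 0,
    extractor: Optional[FeatureExtractor] = None,
    dark_is_tissue: bool = True,
) -> SlideSegmentation:
    """Full unsupervised sub-region segmentation of a single slide image."""
    img = np.asarray(image)
    gray = img if img.ndim == 2 else img.mean(axis=2)
    thr = otsu_threshold(gray)
    mask = (gray <= thr) if dark_is_tissue else (gray > thr)
    h, w = gray.shape
    tiles = tile_grid(w, h, window=window, stride=stride)
    tiles = filter_tissue_tiles(tiles, mask, min_fg_fraction=min_fg_fraction)
    if tiles.shape[0] == 0:
        raise ValidationError("no tissue tiles retained")
    features = extract_tile_features(img, tiles, extractor=extractor)
    cols = select_top_variance(features, min(top_features, features.shape[1]))
    labels = cluster_tiles(
        features[:, cols], n_pcs=n_pcs, resolution=resolution, seed=seed
    )
    label_map = render_label_map(tiles, labels, (h, w))
    tileset = TileSet(
        slide_id=np.array([slide_id] * tiles.shape[0]),
        tiles=tiles,
        features=features,
        labels=labels,
    )
    return SlideSegmentation(
        tileset=tileset,
        selected_features=cols,
        label_map=label_map,
        threshold=thr,
    )
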
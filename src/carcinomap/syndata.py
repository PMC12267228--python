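"""Seeded synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be simulated here, with the planted
structure returned alongside the data so each downstream stage has a
recoverable target:

* :func:`generate_st_dataset` — negative-binomial spot counts on a spatial
  grid with a latent pseudotemporal gradient, cluster-specific marker genes
  and logistic switch genes;
* :func:`generate_tile_features` — tile feature matrices with a planted
  discriminative feature subset, class effect and slide-level batch shifts;
* :func:`generate_bimodal_image` — blob-shaped two-level grayscale images
  (fixtures for tissue masking);
* :func:`generate_ihc_table` — Dirichlet staining-percentage tables for
  H-score computation.

All generators are fully reproducible: identical config + seed gives
byte-identical output.  Randomness is derived from the config seed via
:mod:`carcinomap._random`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ._random import child_rng
from .datatypes import SpotDataset, TileSet, ValidationError

# Expression levels (expected counts) for the binary states of planted switch
# genes: clearly bimodal after log-normalization, as the switch-detection
# model assumes.
SWITCH_ON_MEAN = 5.0
SWITCH_OFF_MEAN = 0.1


@dataclass
class STSimConfig:
    """Configuration of the spatial-transcriptomic simulation.

    The simulated tissue is a rectangular grid of spots with a latent time
    ``t`` increasing along ``gradient_axis`` (normalized coordinate in
    [0, 1]).  Clusters are contiguous blocks along the gradient, so the
    cluster sequence is also a lineage; switch genes flip state at equally
    spaced times, alternating on- and off-direction.
    """

    n_spots_per_cluster: int = 200
    n_clusters: int = 3
    n_genes: int = 2000
    n_markers_per_cluster: int = 50
    marker_fold: float = 4.0
    nb_dispersion: float = 2.0
    libsize_sigma: float = 0.2
    grid_shape: Tuple[int, int] = (20, 30)
    gradient_axis: str = "x"
    n_switch_genes: int = 50
    switch_slope: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValidationError("n_clusters must be >= 1")
        for name in ("n_spots_per_cluster", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_markers_per_cluster < 0 or self.n_switch_genes < 0:
            raise ValidationError("gene counts must be non-negative")
        if self.marker_fold <= 1:
            raise ValidationError("marker_fold must be > 1")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        if self.gradient_axis not in ("x", "y"):
            raise ValidationError("gradient_axis must be 'x' or 'y'")
        n_special = (
            self.n_clusters * self.n_markers_per_cluster + self.n_switch_genes
        )
        if n_special > self.n_genes:
            raise ValidationError(
                f"{n_special} marker+switch genes exceed n_genes={self.n_genes}"
            )

    @property
    def n_spots(self) -> int:
        return self.n_spots_per_cluster * self.n_clusters


@dataclass
class TileSimConfig:
    """Configuration of the tile-feature simulation (case vs control slides)."""

    n_slides_case: int = 12
    n_slides_control: int = 14
    tiles_per_slide: int = 200
    n_features: int = 512
    planted_set: Sequence[int] = field(default_factory=lambda: tuple(range(20)))
    effect_delta: float = 1.5
    batch_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.planted_set = tuple(int(i) for i in self.planted_set)
        if len(self.planted_set) > self.n_features:
            raise ValidationError("planted_set larger than n_features")
        if any(i < 0 or i >= self.n_features for i in self.planted_set):
            raise ValidationError("planted_set indices out of range")
        if self.effect_delta < 0:
            raise ValidationError("effect_delta must be >= 0")
        for name in ("n_slides_case", "n_slides_control", "tiles_per_slide",
                     "n_features"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean mu, dispersion r) with variance mu + mu^2 / r.

    The Poisson limit (dispersion -> infinity) is taken literally when
    ``dispersion`` is infinite.
    """
    if np.isinf(dispersion):
        return rng.poisson(mu)
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p)


def generate_st_dataset(cfg: STSimConfig) -> SpotDataset:
    """Simulate a spot-level dataset with planted clusters, gradient and switches.

    Spots fill grid cells in order of the gradient axis, so latent time
    ``t`` (the normalized gradient-axis coordinate) is monotone over the
    spot ordering, and the K clusters partition ``t`` into contiguous
    blocks.  Returns a :class:`SpotDataset` whose ``truth`` table carries
    per-spot ``cluster`` and ``latent_time`` and whose ``gene_truth`` table
    carries marker and switch annotations.
    """
    rows, cols = cfg.grid_shape
    n = cfg.n_spots
    if rows * cols < n:
        raise ValidationError(
            f"grid {rows}x{cols} too small for {n} spots"
        )
    rng = child_rng(cfg.seed, "st")

    # Grid placement: axis-major order so latent time is monotone.
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    if cfg.gradient_axis == "x":
        order = np.lexsort((rr.ravel(), cc.ravel()))
        axis_len = cols
    else:
        order = np.lexsort((cc.ravel(), rr.ravel()))
        axis_len = rows
    cells = order[:n]
    array_row = rr.ravel()[cells]
    array_col = cc.ravel()[cells]
    axis_coord = array_col if cfg.gradient_axis == "x" else array_row
    latent_time = axis_coord / max(axis_len - 1, 1)
    cluster = np.repeat(np.arange(cfg.n_clusters), cfg.n_spots_per_cluster)

    # Gene programme: baseline means, cluster markers, switch genes.
    G, K, m = cfg.n_genes, cfg.n_clusters, cfg.n_markers_per_cluster
    baseline = rng.gamma(shape=2.0, scale=0.5, size=G)
    marker_home = np.full(G, -1)
    for c in range(K):
        marker_home[c * m:(c + 1) * m] = c
    # Markers emulate canonical cell-type genes: clearly detectable, so
    # their baseline expression is floored at one expected count.
    baseline[marker_home >= 0] = np.maximum(baseline[marker_home >= 0], 1.0)
    n_sw = cfg.n_switch_genes
    sw_start = K * m
    is_switch = np.zeros(G, bool)
    is_switch[sw_start:sw_start + n_sw] = True
    switch_time = np.full(G, np.nan)
    switch_dir = np.array([""] * G, dtype=object)
    if n_sw > 0:
        t_stars = (np.arange(n_sw) + 1) / (n_sw + 1)
        switch_time[sw_start:sw_start + n_sw] = t_stars
        switch_dir[sw_start:sw_start + n_sw] = [
            "on" if j % 2 == 0 else "off" for j in range(n_sw)
        ]

    # Expected counts per (gene, spot).
    mu = np.tile(baseline[:, None], (1, n))
    for g in range(K * m):
        home = marker_home[g]
        mu[g, cluster == home] *= cfg.marker_fold
    switch_state = np.zeros((n_sw, n), dtype=np.int8)
    for j in range(n_sw):
        g = sw_start + j
        s = cfg.switch_slope if switch_dir[g] == "on" else -cfg.switch_slope
        p_on = 1.0 / (1.0 + np.exp(-s * (latent_time - switch_time[g])))
        state = rng.random(n) < p_on
        switch_state[j] = state
        mu[g] = np.where(state, SWITCH_ON_MEAN, SWITCH_OFF_MEAN)

    libsize = np.exp(rng.normal(0.0, cfg.libsize_sigma, size=n))
    counts = _nb_draw(rng, mu * libsize[None, :], cfg.nb_dispersion)

    spot_ids = np.array([f"spot_{i:05d}" for i in range(n)])
    gene_ids = np.array([f"gene_{g:05d}" for g in range(G)])
    coords = pd.DataFrame(
        {
            "array_row": array_row,
            "array_col": array_col,
            "pixel_x": array_col * 100.0,
            "pixel_y": array_row * 100.0,
        },
        index=pd.Index(spot_ids, name="barcode"),
    )
    truth = pd.DataFrame(
        {"cluster": cluster, "latent_time": latent_time},
        index=coords.index,
    )
    gene_truth = pd.DataFrame(
        {
            "baseline_mean": baseline,
            "marker_home_cluster": marker_home,
            "is_switch": is_switch,
            "switch_time": switch_time,
            "switch_direction": switch_dir,
        },
        index=pd.Index(gene_ids, name="gene"),
    )
    return SpotDataset(
        counts=counts.astype(np.int64),
        gene_ids=gene_ids,
        spot_ids=spot_ids,
        coords=coords,
        sample_label=np.array(["sample0"] * n),
        truth=truth,
        gene_truth=gene_truth,
    )


def generate_tile_features(cfg: TileSimConfig) -> TileSet:
    """Simulate tile features for case/control slides.

    Features are standard normal; case tiles get ``effect_delta`` added on
    the planted feature subset; every slide contributes an additive
    Normal(0, batch_sigma) shift shared by all its tiles.  Each slide's
    tiles are split into two ROIs (first half / second half) whose ground
    truth label is the slide label.
    """
    rng = child_rng(cfg.seed, "tiles")
    slide_names = [f"case_{i:02d}" for i in range(cfg.n_slides_case)] + [
        f"control_{i:02d}" for i in range(cfg.n_slides_control)
    ]
    slide_class = np.array(
        [1] * cfg.n_slides_case + [0] * cfg.n_slides_control
    )
    n_slides = len(slide_names)
    tps = cfg.tiles_per_slide
    n_tiles = n_slides * tps
    D = cfg.n_features

    features = rng.standard_normal((n_tiles, D))
    batch_shift = rng.normal(0.0, cfg.batch_sigma, size=(n_slides, D))
    planted = np.array(cfg.planted_set, dtype=int)

    slide_id = np.repeat(slide_names, tps)
    labels = np.repeat(slide_class, tps)
    for s in range(n_slides):
        block = slice(s * tps, (s + 1) * tps)
        features[block] += batch_shift[s]
        if slide_class[s] == 1 and planted.size:
            features[block][:, planted] += cfg.effect_delta

    # Tile geometry: non-overlapping 256 px tiles laid row-major per slide.
    per_row = int(np.ceil(np.sqrt(tps)))
    idx = np.arange(tps)
    xywh = np.column_stack(
        [
            (idx % per_row) * 256,
            (idx // per_row) * 256,
            np.full(tps, 256),
            np.full(tps, 256),
        ]
    )
    tiles = np.tile(xywh, (n_slides, 1))
    roi_id = np.concatenate(
        [
            np.where(idx < tps // 2, f"{name}_roi0", f"{name}_roi1")
            for name in slide_names
        ]
    )
    return TileSet(
        slide_id=slide_id,
        tiles=tiles,
        roi_id=roi_id,
        features=features,
        labels=labels,
        truth={
            "planted_features": planted,
            "slide_class": dict(zip(slide_names, slide_class.tolist())),
        },
    )


def generate_bimodal_image(
    width: int,
    height: int,
    fg_level: int = 60,
    bg_level: int = 220,
    fg_fraction: float = 0.3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Blob-shaped two-level grayscale image plus its foreground mask.

    A smoothed Gaussian random field is thresholded at the
    ``1 - fg_fraction`` quantile, so the foreground covers approximately
    ``fg_fraction`` of pixels and forms connected blobs (tissue-like).
    Returns ``(image uint8, foreground mask bool)``.
    """
    if not (0 < fg_fraction < 1):
        raise ValidationError("fg_fraction must lie in (0, 1)")
    for level in (fg_level, bg_level):
        if not (0 <= level <= 255):
            raise ValidationError("levels must lie in [0, 255]")
    rng = child_rng(seed, "image")
    field_ = gaussian_filter(
        rng.standard_normal((height, width)), sigma=max(min(height, width) / 8, 1)
    )
    thresh = np.quantile(field_, 1 - fg_fraction)
    mask = field_ >= thresh
    img = np.where(mask, float(fg_level), float(bg_level))
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, mask


def generate_ihc_table(
    n_samples: int,
    intensity_dirichlet: Sequence[float] = (1.0, 1.0, 1.0, 1.0),
    seed: int = 0,
    group: Optional[str] = None,
) -> pd.DataFrame:
    """Staining-percentage table over intensity categories {0, 1, 2, 3}.

    Each row holds percentages (summing to 100) drawn from a Dirichlet with
    the given 4 concentration parameters.  ``group`` optionally tags all
    rows with a group label.
    """
    conc = np.asarray(intensity_dirichlet, dtype=float)
    if conc.shape != (4,):
        raise ValidationError("intensity_dirichlet needs exactly 4 parameters")
    if np.any(conc <= 0):
        raise ValidationError("Dirichlet concentrations must be positive")
    rng = child_rng(seed, "ihc")
    if n_samples == 0:
        frac = np.zeros((0, 4))
    else:
        frac = rng.dirichlet(conc, size=n_samples)
    table = pd.DataFrame(
        frac * 100.0, columns=["p0", "p1", "p2", "p3"]
    )
    table.insert(0, "sample_id", [f"sample_{i:03d}" for i in range(n_samples)])
    if group is not None:
        table.insert(1, "group", group)
    return table
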
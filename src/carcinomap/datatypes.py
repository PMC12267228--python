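"""Shared in-memory containers for the pipeline stages.

Conventions used throughout the package:

* expression matrices are genes x spots (rows = genes), counts are
  non-negative integers;
* image/tile coordinates are 0-based with the origin at the top-left and
  half-open boxes ``[x, x + w) x [y, y + h)``;
* spot positions follow the Visium-style table
  (barcode, array_row, array_col, pixel_x, pixel_y).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass
class SpotDataset:
    """Spot-level expression with spatial coordinates.

    Parameters
    ----------
    counts
        Dense genes x spots matrix of non-negative integer UMI counts.
    gene_ids, spot_ids
        Row / column identifiers, unique.
    coords
        Per-spot table indexed like ``spot_ids`` with columns
        ``array_row, array_col, pixel_x, pixel_y``.
    sample_label
        Per-spot sample / batch identifier.
    layers
        Named derived matrices (e.g. the normalized layer), same shape as
        ``counts``.
    truth
        Optional planted ground truth per spot (``cluster``, ``latent_time``).
    gene_truth
        Optional planted ground truth per gene (marker home cluster, switch
        time / direction).
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    spot_ids: np.ndarray
    coords: pd.DataFrame
    sample_label: np.ndarray
    layers: dict = field(default_factory=dict)
    truth: Optional[pd.DataFrame] = None
    gene_truth: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = np.asarray(self.gene_ids)
        self.spot_ids = np.asarray(self.spot_ids)
        self.sample_label = np.asarray(self.sample_label)
        g, s = self.counts.shape
        if len(self.gene_ids) != g:
            raise ValidationError(
                f"gene_ids length {len(self.gene_ids)} != {g} matrix rows"
            )
        if len(self.spot_ids) != s:
            raise ValidationError(
                f"spot_ids length {len(self.spot_ids)} != {s} matrix columns"
            )
        if len(self.sample_label) != s:
            raise ValidationError("sample_label must have one entry per spot")
        if len(self.coords) != s:
            raise ValidationError("coords must have one row per spot")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    def subset_spots(self, keep: np.ndarray) -> "SpotDataset":
        """Return a new dataset restricted to the given spot mask/indices."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return SpotDataset(
            counts=self.counts[:, keep].copy(),
            gene_ids=self.gene_ids.copy(),
            spot_ids=self.spot_ids[keep].copy(),
            coords=self.coords.iloc[keep].copy(),
            sample_label=self.sample_label[keep].copy(),
            layers={k: v[:, keep].copy() for k, v in self.layers.items()},
            truth=None if self.truth is None else self.truth.iloc[keep].copy(),
            gene_truth=None if self.gene_truth is None else self.gene_truth.copy(),
        )

    def subset_genes(self, keep: np.ndarray) -> "SpotDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return SpotDataset(
            counts=self.counts[keep].copy(),
            gene_ids=self.gene_ids[keep].copy(),
            spot_ids=self.spot_ids.copy(),
            coords=self.coords.copy(),
            sample_label=self.sample_label.copy(),
            layers={k: v[keep].copy() for k, v in self.layers.items()},
            truth=None if self.truth is None else self.truth.copy(),
            gene_truth=(
                None if self.gene_truth is None else self.gene_truth.iloc[keep].copy()
            ),
        )

    def to_anndata(self):
        """Export as an :class:`anndata.AnnData` (spots x genes)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.T.astype(np.float64),
            obs=self.coords.copy().assign(sample=self.sample_label),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene")),
        )
        for name, layer in self.layers.items():
            adata.layers[name] = layer.T.copy()
        if self.truth is not None:
            for col in self.truth.columns:
                adata.obs[f"truth_{col}"] = np.asarray(self.truth[col])
        return adata


@dataclass
class TileSet:
    """Tiles cut from one or more slides plus an optional feature matrix.

    ``tiles`` holds one row per tile: (x, y, w, h) in level-0 pixels.
    """

    slide_id: np.ndarray
    tiles: np.ndarray
    microns_per_pixel: float = 0.5
    roi_id: Optional[np.ndarray] = None
    features: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.slide_id = np.asarray(self.slide_id)
        self.tiles = np.asarray(self.tiles)
        if self.tiles.ndim != 2 or self.tiles.shape[1] != 4:
            raise ValidationError("tiles must be an (n, 4) array of (x, y, w, h)")
        n = self.tiles.shape[0]
        if len(self.slide_id) != n:
            raise ValidationError("slide_id must have one entry per tile")
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=np.float64)
            if self.features.shape[0] != n:
                raise ValidationError(
                    f"features rows {self.features.shape[0]} != tile count {n}"
                )
        if self.roi_id is not None:
            self.roi_id = np.asarray(self.roi_id)
            if len(self.roi_id) != n:
                raise ValidationError("roi_id must have one entry per tile")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != n:
                raise ValidationError("labels must have one entry per tile")

    @property
    def n_tiles(self) -> int:
        return self.tiles.shape[0]
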
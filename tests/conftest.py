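"""Shared fixtures: small and default-scale synthetic datasets.

Everything is generated at test time from seeded configs; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from carcinomap import STSimConfig, TileSimConfig, syndata, st_core


@pytest.fixture(scope="session")
def st_small():
    """Fast K=3 dataset (150 spots, 300 genes), QC'd and normalized."""
    cfg = STSimConfig(
        n_spots_per_cluster=50,
        n_genes=300,
        n_markers_per_cluster=20,
        grid_shape=(10, 15),
        n_switch_genes=10,
        seed=0,
    )
    ds = syndata.generate_st_dataset(cfg)
    ds, _ = st_core.qc_filter(ds, min_genes=1, min_umi=1)
    return st_core.normalize_log(ds)


@pytest.fixture(scope="session")
def st_default():
    """The default simulation: K=3 x 200 spots, 2000 genes, 50 switch genes."""
    ds = syndata.generate_st_dataset(STSimConfig())
    ds, _ = st_core.qc_filter(ds, min_genes=1, min_umi=1)
    return st_core.normalize_log(ds)


@pytest.fixture(scope="session")
def tiles_default():
    """Default case/control tile features: 12+14 slides x 200 tiles, 512
    features, 20 planted at delta 1.5, slide batch sigma 0.5."""
    return syndata.generate_tile_features(TileSimConfig())


def make_two_group_counts(
    n_genes=2000,
    n_per_group=100,
    up=(),
    down=(),
    fc=3.0,
    dispersion=2.0,
    seed=0,
):
    """Direct NB two-group counts with planted fold changes (test helper)."""
    import pandas as pd

    from carcinomap.datatypes import SpotDataset

    rng = np.random.default_rng(seed)
    baseline = np.maximum(rng.gamma(2.0, 0.5, size=n_genes), 0.3)
    n = 2 * n_per_group
    mu = np.tile(baseline[:, None], (1, n))
    group_a = np.arange(n_per_group)
    mu[np.ix_(list(up), group_a)] *= fc
    mu[np.ix_(list(down), group_a)] /= fc
    p = dispersion / (dispersion + mu)
    counts = rng.negative_binomial(dispersion, p)
    spot_ids = np.array([f"s{i:04d}" for i in range(n)])
    coords = pd.DataFrame(
        {
            "array_row": np.zeros(n, int),
            "array_col": np.arange(n),
            "pixel_x": np.arange(n) * 10.0,
            "pixel_y": np.zeros(n),
        },
        index=pd.Index(spot_ids, name="barcode"),
    )
    ds = SpotDataset(
        counts=counts,
        gene_ids=np.array([f"g{i:04d}" for i in range(n_genes)]),
        spot_ids=spot_ids,
        coords=coords,
        sample_label=np.array(["s0"] * n),
    )
    ds = st_core.normalize_log(ds)
    masks = (np.arange(n) < n_per_group, np.arange(n) >= n_per_group)
    return ds, masks[0], masks[1]
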
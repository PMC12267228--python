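"""Two-group differential expression and hypergeometric gene-set enrichment.

Differential genes are called with a Wilcoxon rank-sum test by default (the
bimod LRT is available for consistency with marker detection).  Fold change
is computed on the linear scale, from de-logged (``expm1``) means of the
normalized layer with a small pseudocount, and the fold-change filter is
applied two-sidedly: up at FC > fc_min, down at FC < 1/fc_min.  Filtering
uses the raw p-value (BH q-values are reported alongside).

Gene-set enrichment is the one-sided hypergeometric tail
``P(X >= k)`` for overlap ``k`` between the hit list and each set, within a
stated gene universe, BH-corrected across sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import SpotDataset, ValidationError

_PSEUDO = 1e-9


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs propagate with a warning."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    nan_mask = np.isnan(p)
    if np.any((p[~nan_mask] < 0) | (p[~nan_mask] > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if nan_mask.any():
        warnings.warn(
            f"{int(nan_mask.sum())} NaN p-values propagated unadjusted",
            stacklevel=2,
        )
    valid = ~nan_mask
    if valid.any():
        q[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return q


def fold_change_from_lognorm(
    group_a: np.ndarray, group_b: np.ndarray, pseudocount: float = _PSEUDO
) -> np.ndarray:
    """Linear fold change A/B from log1p-normalized values (per gene row)."""
    mean_a = np.expm1(group_a).mean(axis=1)
    mean_b = np.expm1(group_b).mean(axis=1)
    return (mean_a + pseudocount) / (mean_b + pseudocount)


@dataclass
class DEGTable:
    """Differential-expression result with the thresholds used."""

    table: pd.DataFrame
    p_max: float
    fc_min: float

    @property
    def n_up(self) -> int:
        return int(
            (self.table["passed_filter"] & (self.table["direction"] == "up")).sum()
        )

    @property
    def n_down(self) -> int:
        return int(
            (self.table["passed_filter"] & (self.table["direction"] == "down")).sum()
        )

    def passed(self) -> pd.DataFrame:
        return self.table[self.table["passed_filter"]]


def find_degs(
    ds: SpotDataset,
    group_a: np.ndarray,
    group_b: np.ndarray,
    p_max: float = 0.05,
    fc_min: float = 1.5,
    test: str = "wilcoxon",
    layer: str = "lognorm",
) -> DEGTable:
    """Differential expression between two disjoint spot groups.

    ``group_a`` / ``group_b`` are boolean masks or index arrays over spots;
    direction is relative to group A (up = higher in A).
    """
    from .st_core import bimod_lrt

    if layer not in ds.layers:
        raise ValidationError(f"layer '{layer}' missing; run normalize_log")
    if fc_min <= 1:
        raise ValidationError("fc_min must be > 1")

    def _as_idx(g):
        g = np.asarray(g)
        return np.flatnonzero(g) if g.dtype == bool else g.astype(int)

    ia, ib = _as_idx(group_a), _as_idx(group_b)
    if ia.size == 0 or ib.size == 0:
        raise ValidationError("both groups must be non-empty")
    if np.intersect1d(ia, ib).size:
        raise ValidationError("groups must be disjoint")

    X = ds.layers[layer]
    Xa, Xb = X[:, ia], X[:, ib]
    fc = fold_change_from_lognorm(Xa, Xb)

    if test == "wilcoxon":
        pvals = np.empty(ds.n_genes)
        for g in range(ds.n_genes):
            a, b = Xa[g], Xb[g]
            if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
                pvals[g] = 1.0
            else:
                pvals[g] = stats.mannwhitneyu(
                    a, b, alternative="two-sided", method="asymptotic"
                ).pvalue
    elif test == "bimod":
        pvals = np.array([bimod_lrt(Xa[g], Xb[g])[1] for g in range(ds.n_genes)])
    else:
        raise ValidationError(f"unknown test '{test}'")

    q = bh_adjust(pvals)
    with np.errstate(divide="ignore"):
        log2_fc = np.where(fc > 0, np.log2(np.maximum(fc, 1e-300)), -np.inf)
    direction = np.where(fc >= 1, "up", "down")
    passed = (pvals < p_max) & ((fc > fc_min) | (fc < 1.0 / fc_min))
    table = pd.DataFrame(
        {
            "gene": ds.gene_ids,
            "fold_change": fc,
            "log2_fc": log2_fc,
            "p": pvals,
            "q": q,
            "direction": direction,
            "passed_filter": passed,
        }
    )
    return DEGTable(table=table, p_max=p_max, fc_min=fc_min)


@dataclass
class EnrichmentResult:
    set_name: str
    set_size: int
    universe_size: int
    draw_size: int
    overlap: int
    p_hyper: float
    q: float
    overlap_genes: tuple


def hypergeom_pval(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k) for overlap k.

    N = universe size, K = set size, n = number of hits drawn.
    """
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    hit_genes: Sequence[str],
    gene_sets: Dict[str, Sequence[str]],
    universe: Sequence[str],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of each gene set in the hit list.

    Sets are intersected with the universe first; sets with no overlap with
    the universe are skipped with a warning.  Results are BH-corrected
    across tested sets and sorted by p.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValidationError("empty gene universe")
    hits = set(hit_genes)
    if not hits <= universe_set:
        raise ValidationError("hit genes must be a subset of the universe")
    N, n = len(universe_set), len(hits)
    rows = []
    for name, genes in gene_sets.items():
        members = set(genes) & universe_set
        if not members:
            warnings.warn(
                f"gene set '{name}' has no overlap with the universe; skipped",
                stacklevel=2,
            )
            continue
        overlap = sorted(hits & members)
        rows.append((name, len(members), len(overlap), tuple(overlap)))
    pvals = np.array([hypergeom_pval(N, K, n, k) for _, K, k, _ in rows])
    qvals = bh_adjust(pvals) if rows else np.array([])
    results = [
        EnrichmentResult(
            set_name=name,
            set_size=K,
            universe_size=N,
            draw_size=n,
            overlap=k,
            p_hyper=float(p),
            q=float(q),
            overlap_genes=genes,
        )
        for (name, K, k, genes), p, q in zip(rows, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.p_hyper, r.set_name))
    return results


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "set_size": r.set_size,
                "universe_size": r.universe_size,
                "draw_size": r.draw_size,
                "overlap": r.overlap,
                "p_hyper": r.p_hyper,
                "q": r.q,
                "overlap_genes": ";".join(r.overlap_genes),
            }
            for r in results
        ]
    )


def volcano_data(deg: DEGTable) -> pd.DataFrame:
    """Volcano-plot export: gene, log2 fold change and -log10 p."""
    t = deg.table
    with np.errstate(divide="ignore"):
        neglog = -np.log10(np.maximum(t["p"].to_numpy(), 1e-300))
    return pd.DataFrame(
        {"gene": t["gene"], "log2_fc": t["log2_fc"], "neg_log10_p": neglog}
    )
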
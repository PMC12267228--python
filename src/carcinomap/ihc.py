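"""Immunohistochemistry H-score quantification and group comparison.

The H-score of a sample is ``sum_i P_i * i`` over staining-intensity
categories i in {0 (none), 1 (weak), 2 (moderate), 3 (strong)}, with P_i
the percentage of cells in category i; it ranges 0-300.  Group comparison
uses the classical pooled-variance unpaired two-tailed Student's t-test
with significance stars at 0.05 (*) and 0.01 (**).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ValidationError

_SUM_TOL = 1e-6


def compute_hscore(percentages: Sequence[float]) -> float:
    """H-score from percentages over intensities 0..3 (must sum to 100)."""
    p = np.asarray(percentages, dtype=np.float64)
    if p.shape != (4,):
        raise ValidationError("exactly 4 intensity percentages required")
    if np.any(p < 0):
        raise ValidationError("percentages must be non-negative")
    total = float(p.sum())
    if abs(total - 100.0) > _SUM_TOL:
        raise ValidationError(
            f"percentages sum to {total!r}, expected 100 (tolerance {_SUM_TOL})"
        )
    return float(np.dot(p, np.arange(4)))


def hscore_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add an ``h_score`` column to a table with columns p0..p3."""
    out = table.copy()
    out["h_score"] = [
        compute_hscore(row) for row in out[["p0", "p1", "p2", "p3"]].to_numpy()
    ]
    return out


@dataclass
class GroupComparison:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    p_value: float
    stars: str
    n_a: int
    n_b: int


def significance_stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> GroupComparison:
    """Unpaired two-tailed Student's t-test (equal variances) on H-scores."""
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 samples")
    res = stats.ttest_ind(a, b, equal_var=True)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # zero pooled variance with equal means
        t, p = 0.0, 1.0
    return GroupComparison(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        t_statistic=t,
        p_value=p,
        stars=significance_stars(p),
        n_a=a.size,
        n_b=b.size,
    )


def compare_hscore_table(table: pd.DataFrame, group_col: str = "group"
                         ) -> GroupComparison:
    """Compare H-scores between the two groups of a p0..p3 table."""
    scored = hscore_table(table)
    groups = scored[group_col].unique()
    if len(groups) != 2:
        raise ValidationError(f"expected exactly 2 groups, found {list(groups)}")
    a = scored.loc[scored[group_col] == groups[0], "h_score"]
    b = scored.loc[scored[group_col] == groups[1], "h_score"]
    return compare_groups(a.to_numpy(), b.to_numpy())
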
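"""Slide-grouped classification of muscle tiles with ROI-level voting.

Tiles inherit the label of their slide (case vs control).  Evaluation uses
repeated grouped holdout: in each of ``n_iterations`` draws, a fixed number
of case and control slides form the test set and all remaining slides the
training set, so no slide ever contributes tiles to both sides of one
iteration (no leakage).  Test sets avoid reusing slides across iterations
while enough unused slides remain, then fall back to sampling from all
slides.

The classifier is a linear model over tile features: L2-regularized
logistic regression by default (probabilistic scores feed AUC and voting);
a least-squares-on-{0,1} scorer is available as an alternative.  Per-ROI
and per-slide subtype calls are majority votes over hard tile calls at a
score threshold (exact ties resolved by mean score, with >= threshold
counting positive).  Feature importance is summarized across iterations by
intersecting each model's top-k absolute weights (consensus features).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import roc_auc_score

from ._random import child_int, child_rng
from .datatypes import TileSet, ValidationError
from .histoseg import _footprint_slices


# ---------------------------------------------------------------------------
# Fold plan
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Repeated grouped-holdout plan over slides."""

    iterations: list  # of dicts: {"test": [...], "train": [...]}
    seed: int

    def assert_no_leakage(self) -> None:
        for it in self.iterations:
            if set(it["test"]) & set(it["train"]):
                raise AssertionError("slide appears in both train and test")


def make_grouped_folds(
    slide_table: pd.DataFrame,
    n_iterations: int = 5,
    test_case: int = 2,
    test_control: int = 2,
    seed: int = 0,
) -> FoldPlan:
    """Draw seeded grouped holdout folds.

    ``slide_table`` needs columns ``slide_id`` and ``group`` (1/"case" vs
    0/"control").  Test slides are drawn without cross-iteration reuse
    while unused slides remain in a group, then with replacement of earlier
    test slides.
    """
    groups = _slide_groups(slide_table)
    case_ids = sorted(s for s, g in groups.items() if g == 1)
    control_ids = sorted(s for s, g in groups.items() if g == 0)
    if len(case_ids) < test_case or len(control_ids) < test_control:
        raise ValidationError(
            f"need >= {test_case} case and >= {test_control} control slides; "
            f"have {len(case_ids)} / {len(control_ids)}"
        )
    rng = child_rng(seed, "folds")
    used: set = set()
    iterations = []
    for _ in range(n_iterations):
        test = []
        for ids, n_test in ((case_ids, test_case), (control_ids, test_control)):
            fresh = [s for s in ids if s not in used]
            pool = fresh if len(fresh) >= n_test else list(ids)
            pick = sorted(rng.choice(pool, size=n_test, replace=False).tolist())
            test.extend(pick)
            used.update(pick)
        train = sorted((set(case_ids) | set(control_ids)) - set(test))
        iterations.append({"test": sorted(test), "train": train})
    plan = FoldPlan(iterations=iterations, seed=seed)
    plan.assert_no_leakage()
    return plan


def _slide_groups(slide_table: pd.DataFrame) -> dict:
    def _as_int(g):
        if isinstance(g, str):
            return 1 if g.lower() in ("case", "model", "1", "experimental") else 0
        return int(g)

    return {
        str(r["slide_id"]): _as_int(r["group"])
        for _, r in slide_table.iterrows()
    }


# ---------------------------------------------------------------------------
# Linear model
# ---------------------------------------------------------------------------

@dataclass
class LinearTileModel:
    weights: np.ndarray
    intercept: float
    method: str

    def score(self, features: np.ndarray) -> np.ndarray:
        """Per-tile score: logistic probability, or raw least-squares value."""
        z = np.asarray(features) @ self.weights + self.intercept
        if self.method == "logistic":
            return 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))
        return z


def train_linear(
    features: np.ndarray,
    labels: np.ndarray,
    l2: float = 1.0,
    method: str = "logistic",
) -> LinearTileModel:
    """Fit the linear tile classifier (two classes required)."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise ValidationError("training set contains a single class")
    if method == "logistic":
        clf = LogisticRegression(
            C=1.0 / max(l2, 1e-12), solver="lbfgs", max_iter=2000
        )
        clf.fit(X, y)
        return LinearTileModel(
            weights=clf.coef_.ravel().copy(),
            intercept=float(clf.intercept_[0]),
            method="logistic",
        )
    if method == "least_squares":
        reg = LinearRegression()
        reg.fit(X, y.astype(float))
        return LinearTileModel(
            weights=reg.coef_.copy(),
            intercept=float(reg.intercept_),
            method="least_squares",
        )
    raise ValidationError(f"unknown method '{method}'")


# ---------------------------------------------------------------------------
# Voting and AUC
# ---------------------------------------------------------------------------

def vote_roi(
    scores: np.ndarray,
    roi_ids: Sequence,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Majority vote of hard tile calls within each ROI.

    Exact ties are decided by the mean score (>= threshold counts
    positive).  Returns one row per ROI with the label and the fraction of
    tiles voting positive.
    """
    scores = np.asarray(scores, dtype=np.float64)
    roi_ids = np.asarray(roi_ids)
    if scores.size != roi_ids.size:
        raise ValidationError("one ROI id per tile score required")
    if scores.size == 0:
        raise ValidationError("no tiles to vote on")
    rows = []
    for roi in pd.unique(roi_ids):
        sel = scores[roi_ids == roi]
        if sel.size == 0:
            raise ValidationError(f"ROI {roi} has no tiles")
        pos = int((sel >= threshold).sum())
        neg = sel.size - pos
        if pos > neg:
            label = 1
        elif pos < neg:
            label = 0
        else:
            label = int(sel.mean() >= threshold)
        rows.append(
            {
                "roi_id": roi,
                "label": label,
                "positive_fraction": pos / sel.size,
                "mean_score": float(sel.mean()),
                "n_tiles": sel.size,
            }
        )
    return pd.DataFrame(rows)


def auc(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    with_ci: bool = True,
) -> Tuple[float, Optional[Tuple[float, float]]]:
    """AUC (pairwise concordance, ties = 0.5) with a bootstrap 95% CI.

    The CI is a stratified percentile bootstrap: positives and negatives
    are resampled separately so every replicate contains both classes.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise ValidationError("AUC needs both classes")
    value = float(roc_auc_score(labels, scores))
    if not with_ci:
        return value, None
    rng = child_rng(seed, "auc-boot")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    reps = np.empty(n_boot)
    for b in range(n_boot):
        ps = rng.choice(pos, size=pos.size, replace=True)
        ns = rng.choice(neg, size=neg.size, replace=True)
        reps[b] = roc_auc_score(
            np.r_[np.ones(ps.size, int), np.zeros(ns.size, int)], np.r_[ps, ns]
        )
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return value, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Consensus features
# ---------------------------------------------------------------------------

@dataclass
class ConsensusFeatures:
    per_iteration: list  # list of sorted index tuples
    intersection: tuple
    k: int


def consensus_features(
    weight_vectors: Sequence[np.ndarray], k: int = 50
) -> ConsensusFeatures:
    """Intersection of each iteration's top-k absolute weights.

    Ties in |weight| are broken by feature index.
    """
    if len(weight_vectors) == 0:
        raise ValidationError("at least one weight vector required")
    tops = []
    for w in weight_vectors:
        w = np.asarray(w)
        if k > w.size:
            raise ValidationError(f"k={k} exceeds feature count {w.size}")
        order = np.lexsort((np.arange(w.size), -np.abs(w)))
        tops.append(tuple(sorted(int(i) for i in order[:k])))
    inter = set(tops[0])
    for t in tops[1:]:
        inter &= set(t)
    return ConsensusFeatures(
        per_iteration=tops, intersection=tuple(sorted(inter)), k=k
    )


# ---------------------------------------------------------------------------
# Score map
# ---------------------------------------------------------------------------

def tile_score_map(
    scores: np.ndarray,
    tiles: np.ndarray,
    slide_shape: Tuple[int, int],
    downsample: int = 1,
) -> np.ndarray:
    """Per-pixel mean of overlapping tile scores; uncovered pixels are NaN."""
    tiles = np.asarray(tiles)
    scores = np.asarray(scores, dtype=np.float64)
    H = -(-slide_shape[0] // downsample)
    W = -(-slide_shape[1] // downsample)
    total = np.zeros((H, W))
    count = np.zeros((H, W), dtype=np.int32)
    for (x, y, w, h), s in zip(tiles, scores):
        ys, xs = _footprint_slices(x, y, w, h, downsample, H, W)
        total[ys, xs] += s
        count[ys, xs] += 1
    with np.errstate(invalid="ignore"):
        out = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return out


# ---------------------------------------------------------------------------
# End-to-end grouped CV
# ---------------------------------------------------------------------------

@dataclass
class SubtypeCVResult:
    plan: FoldPlan
    per_iteration_auc: list
    pooled_auc: float
    pooled_auc_ci: Tuple[float, float]
    roi_accuracy: float
    slide_accuracy: float
    consensus: ConsensusFeatures
    tile_scores: pd.DataFrame = field(repr=False, default=None)


def run_subtype_cv(
    tileset: TileSet,
    n_iterations: int = 5,
    test_case: int = 2,
    test_control: int = 2,
    l2: float = 1.0,
    top_k_weights: int = 50,
    threshold: float = 0.5,
    method: str = "logistic",
    seed: int = 0,
) -> SubtypeCVResult:
    """Grouped CV of the tile classifier with ROI/slide voting and consensus.

    Requires ``tileset.labels`` (tile = slide class) and ``tileset.roi_id``.
    """
    if tileset.features is None or tileset.labels is None:
        raise ValidationError("tileset needs features and labels")
    if tileset.roi_id is None:
        raise ValidationError("tileset needs roi_id for ROI voting")
    slide_ids = tileset.slide_id
    slide_table = (
        pd.DataFrame({"slide_id": slide_ids, "group": tileset.labels})
        .drop_duplicates("slide_id")
        .reset_index(drop=True)
    )
    plan = make_grouped_folds(
        slide_table,
        n_iterations=n_iterations,
        test_case=test_case,
        test_control=test_control,
        seed=seed,
    )
    groups = _slide_groups(slide_table)
    weights, iter_auc = [], []
    score_rows = []
    for it_idx, it in enumerate(plan.iterations):
        train_mask = np.isin(slide_ids, it["train"])
        test_mask = np.isin(slide_ids, it["test"])
        model = train_linear(
            tileset.features[train_mask],
            tileset.labels[train_mask],
            l2=l2,
            method=method,
        )
        weights.append(model.weights)
        s = model.score(tileset.features[test_mask])
        y = tileset.labels[test_mask]
        iter_auc.append(auc(s, y, with_ci=False)[0])
        for sc, lab, sid, roi in zip(
            s, y, slide_ids[test_mask], tileset.roi_id[test_mask]
        ):
            score_rows.append(
                {
                    "iteration": it_idx,
                    "slide_id": sid,
                    "roi_id": roi,
                    "score": sc,
                    "label": int(lab),
                }
            )
    scores_df = pd.DataFrame(score_rows)
    pooled_auc, ci = auc(
        scores_df["score"].to_numpy(),
        scores_df["label"].to_numpy(),
        seed=child_int(seed, "pooled-auc"),
    )

    # ROI and slide voting accuracy over all test predictions.
    def _vote_accuracy(by: str) -> float:
        correct = total = 0
        for (it_idx, key), sub in scores_df.groupby(["iteration", by]):
            votes = vote_roi(
                sub["score"].to_numpy(), np.repeat("x", len(sub)),
                threshold=threshold,
            )
            truth = int(sub["label"].iloc[0])
            correct += int(votes["label"].iloc[0] == truth)
            total += 1
        return correct / total if total else np.nan

    roi_acc = _vote_accuracy("roi_id")
    slide_acc = _vote_accuracy("slide_id")
    consensus = consensus_features(weights, k=top_k_weights)
    return SubtypeCVResult(
        plan=plan,
        per_iteration_auc=iter_auc,
        pooled_auc=pooled_auc,
        pooled_auc_ci=ci,
        roi_accuracy=roi_acc,
        slide_accuracy=slide_acc,
        consensus=consensus,
        tile_scores=scores_df,
    )
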
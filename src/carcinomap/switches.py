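"""Switch-gene detection along pseudotime.

Expression is binarized per gene with a 2-component Gaussian mixture on the
normalized values (threshold at the posterior crossover, falling back to
"value > 0" when the mixture is degenerate).  Each gene's binary state is
then regressed on pseudotime with a ridge-stabilized logistic fit
``P(on) = logistic(b0 + b1 * tau)``: the switch time is ``t* = -b0 / b1``
(clamped to [0, 1]), the direction is "on" for positive slope, and fit
quality is McFadden's pseudo-R^2 with a Wald p-value on the slope,
BH-corrected across genes.

The tiny ridge penalty (1e-6) keeps estimates finite under perfect
separation, which is the expected behavior of an ideal switch gene; such
fits are flagged rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from ._random import child_int
from .datatypes import ValidationError
from .diffexpr import bh_adjust

RIDGE_EPS = 1e-6
#: |slope| beyond which a fit is treated as (numerically) separated.
DEGENERATE_SLOPE = 100.0
#: Mixture fallback rules: minimum component weight and mean separation.
MIN_COMPONENT_WEIGHT = 0.05
MIN_MEAN_SEPARATION = 0.1


@dataclass
class SwitchGene:
    """Per-gene logistic on/off fit along pseudotime."""

    gene: str
    direction: str            # "on" (b1 > 0) or "off"
    switch_time: float        # t* = -b0/b1 clamped to [0, 1]
    slope: float
    intercept: float
    pseudo_r2: float
    p: float
    q: float = np.nan
    flagged_degenerate: bool = False


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------

def binarize_gene(
    values: np.ndarray, seed: int = 0
) -> Tuple[np.ndarray, float, bool]:
    """Binarize one gene's normalized values.

    Returns ``(states bool, threshold, degenerate_flag)``.  The threshold is
    the posterior crossover of a 2-component Gaussian mixture; the fallback
    (flagged) is ``value > 0`` when a component is tiny, the means nearly
    coincide, or the gene is constant.
    """
    x = np.asarray(values, dtype=np.float64)
    if np.all(x == x[0]):
        return x > 0, 0.0, True
    if np.unique(x).size < 3:
        return x > 0, 0.0, True
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        random_state=child_int(seed, "binarize"),
        n_init=1,
        max_iter=200,
        reg_covar=1e-6,
    )
    gm.fit(x.reshape(-1, 1))
    means = gm.means_.ravel()
    weights = gm.weights_.ravel()
    lo, hi = np.argsort(means)
    if weights.min() < MIN_COMPONENT_WEIGHT or (
        means[hi] - means[lo] < MIN_MEAN_SEPARATION
    ):
        return x > 0, 0.0, True
    # Posterior crossover between the two means, located on a fine grid.
    grid = np.linspace(means[lo], means[hi], 1025)
    post_hi = gm.predict_proba(grid.reshape(-1, 1))[:, hi]
    above = np.flatnonzero(post_hi >= 0.5)
    threshold = float(grid[above[0]]) if above.size else float(means[hi])
    return x > threshold, threshold, False


def binarize(
    matrix: np.ndarray, seed: int = 0
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binarize a genes x spots normalized matrix.

    Returns ``(states bool matrix, thresholds, degenerate flags)``.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    states = np.zeros(matrix.shape, dtype=bool)
    thresholds = np.zeros(matrix.shape[0])
    flags = np.zeros(matrix.shape[0], dtype=bool)
    for g in range(matrix.shape[0]):
        states[g], thresholds[g], flags[g] = binarize_gene(matrix[g], seed=seed)
    return states, thresholds, flags


# ---------------------------------------------------------------------------
# Ridge logistic fit
# ---------------------------------------------------------------------------

def _ridge_logistic(
    y: np.ndarray, tau: np.ndarray, eps: float = RIDGE_EPS
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Newton (IRLS) fit of logistic y ~ b0 + b1*tau with ridge penalty eps.

    Returns ``(beta, covariance, log_likelihood)``; the covariance is the
    inverse penalized observed information.
    """
    X = np.column_stack([np.ones_like(tau), tau])
    beta = np.zeros(2)
    for _ in range(200):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        W = mu * (1 - mu)
        grad = X.T @ (y - mu) - eps * beta
        H = X.T @ (X * W[:, None]) + eps * np.eye(2)
        step = np.linalg.solve(H, grad)
        # Damp huge steps (near-separated data) to keep the ascent stable.
        step = np.clip(step, -10.0, 10.0)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = np.clip(X @ beta, -700, 700)
    mu = 1.0 / (1.0 + np.exp(-eta))
    ll = float(np.sum(y * np.log(np.maximum(mu, 1e-300))
                      + (1 - y) * np.log(np.maximum(1 - mu, 1e-300))))
    W = mu * (1 - mu)
    H = X.T @ (X * W[:, None]) + eps * np.eye(2)
    cov = np.linalg.inv(H)
    return beta, cov, ll


def fit_switch(
    binary_states: np.ndarray,
    tau: np.ndarray,
    gene: str = "",
) -> Optional[SwitchGene]:
    """Fit the logistic switch model for one gene.

    Returns ``None`` when only one state is present (no fit possible; the
    caller records the gene as flagged/unfit).
    """
    y = np.asarray(binary_states, dtype=np.float64)
    tau = np.asarray(tau, dtype=np.float64)
    ok = ~np.isnan(tau)
    y, tau = y[ok], tau[ok]
    if y.size == 0 or np.all(y == y[0]):
        return None
    beta, cov, ll = _ridge_logistic(y, tau)
    b0, b1 = float(beta[0]), float(beta[1])
    # Null (intercept-only) log-likelihood for McFadden's pseudo-R^2.
    p_bar = y.mean()
    ll0 = float(
        y.size * (p_bar * np.log(p_bar) + (1 - p_bar) * np.log(1 - p_bar))
    )
    pseudo_r2 = float(np.clip(1.0 - ll / ll0, 0.0, 1.0)) if ll0 < 0 else 0.0
    se = float(np.sqrt(cov[1, 1]))
    z = b1 / se if se > 0 else np.inf
    p = float(2 * stats.norm.sf(abs(z)))
    t_star_raw = -b0 / b1 if b1 != 0 else np.nan
    flagged = bool(abs(b1) > DEGENERATE_SLOPE)
    if not np.isfinite(t_star_raw):
        flagged = True
        t_star = 0.0
    else:
        t_star = float(np.clip(t_star_raw, 0.0, 1.0))
        if not (0.0 <= t_star_raw <= 1.0):
            flagged = True  # switches outside the observed trajectory
    return SwitchGene(
        gene=gene,
        direction="on" if b1 > 0 else "off",
        switch_time=t_star,
        slope=b1,
        intercept=b0,
        pseudo_r2=pseudo_r2,
        p=p,
        flagged_degenerate=flagged,
    )


def detect_switches(
    matrix: np.ndarray,
    tau: np.ndarray,
    gene_ids: np.ndarray,
    seed: int = 0,
) -> pd.DataFrame:
    """Binarize a normalized genes x spots matrix and fit every switch.

    Returns one row per gene (unfit genes appear with NaN estimates and
    ``flagged_degenerate=True``); q is BH across the fitted genes.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    tau = np.asarray(tau, dtype=np.float64)
    if matrix.shape[1] != tau.size:
        raise ValidationError("tau must have one value per spot")
    states, thresholds, bin_flags = binarize(matrix, seed=seed)
    rows = []
    for g in range(matrix.shape[0]):
        fit = fit_switch(states[g], tau, gene=str(gene_ids[g]))
        if fit is None:
            rows.append(
                dict(
                    gene=str(gene_ids[g]), direction="", switch_time=np.nan,
                    slope=np.nan, intercept=np.nan, pseudo_r2=np.nan,
                    p=np.nan, flagged_degenerate=True,
                    binarize_threshold=thresholds[g],
                )
            )
        else:
            rows.append(
                dict(
                    gene=fit.gene, direction=fit.direction,
                    switch_time=fit.switch_time, slope=fit.slope,
                    intercept=fit.intercept, pseudo_r2=fit.pseudo_r2,
                    p=fit.p,
                    flagged_degenerate=fit.flagged_degenerate or bool(bin_flags[g]),
                    binarize_threshold=thresholds[g],
                )
            )
    table = pd.DataFrame(rows)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # NaN p for unfit genes is expected
        table["q"] = bh_adjust(table["p"].to_numpy())
    return table


def rank_switches(
    table: pd.DataFrame,
    top_n: Optional[int] = None,
    q_max: float = 0.05,
    min_r2: float = 0.2,
) -> pd.DataFrame:
    """Significant switches ordered along the trajectory.

    Keeps unflagged genes with ``q < q_max`` and ``pseudo_r2 >= min_r2``,
    sorted by switch time (ties by gene id); ``top_n`` truncates.
    """
    if table.empty:
        return table.copy()
    keep = (
        (table["q"] < q_max)
        & (table["pseudo_r2"] >= min_r2)
        & (~table["flagged_degenerate"].astype(bool))
    )
    out = table[keep.fillna(False)].sort_values(
        ["switch_time", "gene"], kind="mergesort"
    )
    if top_n is not None:
        out = out.head(top_n)
    return out.reset_index(drop=True)
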
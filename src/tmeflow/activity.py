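"""Regulator activity inference from expression.

TF activities come from a univariate linear model (ULM): for each TF and
sample, the sample's full gene-expression vector is regressed on the TF's
signed regulon weight vector (zero for non-targets) with an intercept, and
the slope t-statistic is the activity. Pathway activities come from the
multivariate analogue (MLM): one joint regression of the sample's
expression on all pathway footprint-weight columns, with per-coefficient
t-statistics as activities. t-statistics are used (rather than raw slopes)
so regulon size is normalized away; |t| is capped at 50, which only binds
on noiseless data where the residual variance collapses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import logger

T_CAP = 50.0
RESID_EPS = 1e-12


def tf_activity_ulm(expr: pd.DataFrame, regulons: pd.DataFrame,
                    min_targets: int = 5) -> pd.DataFrame:
    """TF x sample activity scores from simple regressions on regulon weights."""
    genes = expr.index
    gene_pos = {g: i for i, g in enumerate(genes)}
    Y = expr.values.astype(float)                      # genes x samples
    n = Y.shape[0]
    ybar = Y.mean(axis=0)
    Yc = Y - ybar[None, :]
    sum_yc2 = (Yc ** 2).sum(axis=0)

    rows = {}
    for tf, sub in regulons.groupby("source", sort=True):
        usable = sub[sub["target"].isin(gene_pos)]
        if len(usable) < min_targets:
            logger.info("skipping TF %s: %d usable targets (< %d)", tf, len(usable), min_targets)
            continue
        w = np.zeros(n)
        w[[gene_pos[g] for g in usable["target"]]] = usable["weight"].values
        if not w.any():
            logger.warning("skipping TF %s: all-zero usable weights", tf)
            continue
        wc = w - w.mean()
        denom = float(wc @ wc)
        slope = (wc @ Yc) / denom                       # per sample
        rss = sum_yc2 - slope ** 2 * denom
        rows[tf] = _t_stats(slope, rss, denom, dof=n - 2)
    act = pd.DataFrame(rows, index=expr.columns).T
    act.index.name = "regulator"
    return act


def pathway_activity_mlm(expr: pd.DataFrame, pathway_model: pd.DataFrame) -> pd.DataFrame:
    """Pathway x sample activity scores from one joint regression per sample."""
    shared = pathway_model.index.intersection(expr.index)
    W = pathway_model.loc[shared].values.astype(float)
    names = list(pathway_model.columns)
    n, p = W.shape
    if n <= p + 2:
        raise ValueError(f"need more usable genes ({n}) than pathways + 2 ({p + 2})")
    X = np.column_stack([np.ones(n), W])
    rank = np.linalg.matrix_rank(X)
    if rank < p + 1:
        corr = np.corrcoef(W.T)
        pairs = [(names[i], names[j]) for i in range(p) for j in range(i + 1, p)
                 if abs(corr[i, j]) > 0.999]
        raise ValueError(f"pathway weight matrix is rank deficient; collinear pathways: {pairs}")
    Y = expr.loc[shared].values.astype(float)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y                            # (p+1) x samples
    resid = Y - X @ beta
    rss = (resid ** 2).sum(axis=0)
    dof = n - (p + 1)
    diag = np.diag(xtx_inv)[1:]                         # skip intercept
    out = np.empty((p, Y.shape[1]))
    for j in range(p):
        out[j] = _t_stats(beta[j + 1], rss, 1.0 / diag[j], dof=dof)
    act = pd.DataFrame(out, index=names, columns=expr.columns)
    act.index.name = "regulator"
    return act


def mlm_coefficients(expr: pd.DataFrame, pathway_model: pd.DataFrame) -> pd.DataFrame:
    """Raw MLM regression coefficients (no t-scaling); exposed for testing
    the least-squares algebra on noiseless constructions."""
    shared = pathway_model.index.intersection(expr.index)
    W = pathway_model.loc[shared].values.astype(float)
    X = np.column_stack([np.ones(len(shared)), W])
    beta, *_ = np.linalg.lstsq(X, expr.loc[shared].values.astype(float), rcond=None)
    return pd.DataFrame(beta[1:], index=pathway_model.columns, columns=expr.columns)


def _t_stats(slope: np.ndarray, rss: np.ndarray, denom: float | np.ndarray,
             dof: int) -> np.ndarray:
    """Per-sample t-statistics with the noiseless-data cap."""
    slope = np.asarray(slope, dtype=float)
    rss = np.maximum(np.asarray(rss, dtype=float), 0.0)
    sigma2 = rss / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / np.sqrt(sigma2 / denom)
    exact = sigma2 < RESID_EPS
    t = np.where(exact, np.sign(slope) * T_CAP, t)
    t = np.where(np.asarray(slope) == 0.0, 0.0, t)
    return np.clip(t, -T_CAP, T_CAP)
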
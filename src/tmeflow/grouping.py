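"""Filtering and iterative merging of deconvolution features into subgroups.

Features estimating the same cell type from different engine/signature
combinations are highly redundant. Within each cell type, the currently
most-correlated pair of representatives (max of Pearson r and the
proportionality coefficient rho_p = 2 cov / (var x + var y)) is merged into
a subgroup whose representative is the mean of its z-scored members; the
procedure repeats until no pair reaches the threshold (default 0.70).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import logger


@dataclass
class FeatureSubgroup:
    subgroup_id: str
    cell_type: str
    members: list[str] = field(default_factory=list)


def filter_features(table: pd.DataFrame, zero_prop_max: float = 0.75,
                    min_variance: float = 1e-8) -> pd.DataFrame:
    """Drop features with a high proportion of exact zeros or low variance."""
    if table.shape[1] == 0:
        raise ValueError("empty feature table")
    keep = []
    for fid in table.columns:
        col = table[fid].values
        zero_prop = float(np.mean(col == 0.0))
        var = float(np.var(col))
        if zero_prop > zero_prop_max:
            logger.info("dropping %s: %.0f%% zeros > %.0f%%", fid, 100 * zero_prop, 100 * zero_prop_max)
        elif var < min_variance:
            logger.info("dropping %s: variance %.3g < %.3g", fid, var, min_variance)
        else:
            keep.append(fid)
    if not keep:
        raise ValueError(
            "all features removed by filtering; relax zero_prop_max or min_variance")
    return table[keep]


def proportionality(x, y) -> float:
    """Concordance-style proportionality rho_p = 2 cov(x, y) / (var x + var y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("inputs must be equal-length vectors of length >= 3")
    vx, vy = np.var(x), np.var(y)
    if vx == 0 or vy == 0:
        raise ValueError("proportionality is undefined for constant input")
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    return float(2.0 * cov / (vx + vy))


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def _pair_score(a: np.ndarray, b: np.ndarray) -> float:
    r = float(np.corrcoef(a, b)[0, 1])
    return max(r, proportionality(a, b))


def merge_correlated_features(
    table: pd.DataFrame,
    feature_cell_types: pd.Series,
    threshold: float = 0.70,
) -> tuple[list[FeatureSubgroup], pd.DataFrame]:
    """Iteratively merge redundant same-cell-type features into subgroups.

    Greedy best-pair merging: within each cell type, the pair of current
    representatives with the highest score (max of Pearson and rho_p) at or
    above ``threshold`` is merged, the subgroup representative recomputed as
    the mean of its z-scored member features, and the search repeated until
    no pair reaches the threshold. Ties break lexicographically on the
    smallest member feature id, making the result invariant to input column
    order.

    Returns (subgroups, samples x subgroups score matrix). Merged subgroups
    are named ``<celltype>.subgroup_<k>``; unmerged features keep their id.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    missing = set(table.columns) - set(feature_cell_types.index)
    if missing:
        raise ValueError(f"cell type unknown for features: {sorted(missing)[:5]}")

    subgroups: list[FeatureSubgroup] = []
    scores: dict[str, np.ndarray] = {}
    for ct in sorted(feature_cell_types.loc[list(table.columns)].unique()):
        fids = sorted(fid for fid in table.columns if feature_cell_types[fid] == ct)
        # item key = lexicographically smallest member id (order-invariant)
        items: dict[str, list[str]] = {fid: [fid] for fid in fids}
        zcols = {fid: _zscore(table[fid].values.astype(float)) for fid in fids}
        reps = {fid: zcols[fid] for fid in fids}

        while len(items) > 1:
            best = None
            keys = sorted(items)
            for i, a in enumerate(keys):
                for b in keys[i + 1:]:
                    s = _pair_score(reps[a], reps[b])
                    if s >= threshold and (best is None or s > best[0]):
                        best = (s, a, b)
            if best is None:
                break
            _, a, b = best
            members = sorted(items.pop(a) + items.pop(b))
            key = members[0]
            items[key] = members
            reps = {k: v for k, v in reps.items() if k not in (a, b)}
            reps[key] = np.mean([zcols[m] for m in members], axis=0)

        k = 0
        for key in sorted(items):
            members = items[key]
            if len(members) == 1:
                sgid = members[0]
            else:
                k += 1
                sgid = f"{ct}.subgroup_{k}"
            subgroups.append(FeatureSubgroup(sgid, ct, members))
            scores[sgid] = np.mean([zcols[m] for m in members], axis=0)

    score_df = pd.DataFrame(scores, index=table.index)
    return subgroups, score_df


def subgroup_scores(subgroups: list[FeatureSubgroup], table: pd.DataFrame) -> pd.DataFrame:
    """Recompute per-sample subgroup scores (mean of z-scored members) on a
    feature table — used when projecting stored memberships onto a new cohort."""
    out = {}
    for sg in subgroups:
        missing = [m for m in sg.members if m not in table.columns]
        if missing:
            raise KeyError(f"subgroup {sg.subgroup_id} members missing from table: {missing}")
        z = np.vstack([_zscore(table[m].values.astype(float)) for m in sg.members])
        out[sg.subgroup_id] = z.mean(axis=0)
    return pd.DataFrame(out, index=table.index)
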
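"""Integration of deconvolution subgroups with TF modules into cell type groups.

Subgroups whose scores correlate significantly with at least one TF module
eigengene are clustered — one dendrogram per module group, on the Euclidean
distance between their correlation profiles restricted to that group's
modules, with Ward (ward.D2-style) linkage cut at an absolute height — into
"cell type groups" named ``Dendrogram_<module-group colors>.group_<k>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats

from .io import logger


@dataclass
class CellTypeGroup:
    group_id: str
    module_group: str
    members: list[str] = field(default_factory=list)


def correlate_subgroups_modules(
    subgroup_scores: pd.DataFrame,
    eigengenes: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Pearson r and two-sided p for every (subgroup, module) pair.

    Returns (r matrix, p matrix, surviving subgroup ids). Subgroups with no
    correlation at p < alpha are dropped from downstream clustering.
    """
    shared = subgroup_scores.index.intersection(eigengenes.index)
    if len(shared) < 5:
        raise ValueError("need >= 5 shared samples to correlate subgroups with modules")
    sgs = list(subgroup_scores.columns)
    mods = list(eigengenes.columns)
    R = np.zeros((len(sgs), len(mods)))
    P = np.ones_like(R)
    for i, sg in enumerate(sgs):
        for j, m in enumerate(mods):
            R[i, j], P[i, j] = scipy.stats.pearsonr(
                subgroup_scores.loc[shared, sg], eigengenes.loc[shared, m])
    r_df = pd.DataFrame(R, index=sgs, columns=mods)
    p_df = pd.DataFrame(P, index=sgs, columns=mods)
    surviving = [sg for sg in sgs if (p_df.loc[sg] < alpha).any()]
    dropped = sorted(set(sgs) - set(surviving))
    if dropped:
        logger.info("subgroups with no significant module correlation dropped: %s", dropped)
    return r_df, p_df, surviving


def build_cell_type_groups(
    corr: pd.DataFrame,
    surviving: list[str],
    module_groups: dict[str, list[str]],
    cut_height: float = 5.0,
    cut_mode: str = "absolute",
    cut_quantile: float = 0.75,
) -> list[CellTypeGroup]:
    """Cluster surviving subgroups into cell type groups, one dendrogram per
    module group.

    Distances are Euclidean between correlation-profile rows restricted to
    the module group's columns; linkage is Ward in the ward.D2 sense
    (unsquared input distances, squared update). The tree is cut at the
    absolute height ``cut_height`` (or at the ``cut_quantile`` quantile of
    merge heights with ``cut_mode='quantile'``); clusters are numbered by
    dendrogram leaf order.
    """
    groups: list[CellTypeGroup] = []
    for mg_id, mod_labels in module_groups.items():
        cols = [m for m in mod_labels if m in corr.columns]
        rows = [sg for sg in surviving if sg in corr.index]
        if len(rows) < 2:
            logger.warning("module group %s: fewer than 2 surviving subgroups; single group", mg_id)
            if rows:
                groups.append(CellTypeGroup(f"Dendrogram_{mg_id}.group_1", mg_id, rows))
            continue
        X = corr.loc[rows, cols].values
        Z = sch.linkage(X, method="ward")
        if cut_mode == "quantile":
            t = float(np.quantile(Z[:, 2], cut_quantile))
        else:
            t = cut_height
        labels = sch.fcluster(Z, t=t, criterion="distance")
        if len(set(labels)) == 1:
            logger.warning("module group %s: cut height %.3g yields a single group", mg_id, t)
        order = sch.leaves_list(Z)
        seen: dict[int, int] = {}
        for leaf in order:
            lab = int(labels[leaf])
            if lab not in seen:
                seen[lab] = len(seen) + 1
        for lab, k in sorted(seen.items(), key=lambda kv: kv[1]):
            members = sorted(rows[i] for i in range(len(rows)) if labels[i] == lab)
            groups.append(CellTypeGroup(f"Dendrogram_{mg_id}.group_{k}", mg_id, members))
    return groups


def combine_groups(groups: list[CellTypeGroup], merges: list[list[str]]) -> list[CellTypeGroup]:
    """User-directed post-hoc merges; merged groups get ``group_combined_<k>`` ids."""
    by_id = {g.group_id: g for g in groups}
    out = [g for g in groups]
    for k, ids in enumerate(merges, start=1):
        missing = [i for i in ids if i not in by_id]
        if missing:
            raise KeyError(f"unknown group ids in merge list: {missing}")
        mgs = {by_id[i].module_group for i in ids}
        if len(mgs) != 1:
            raise ValueError("can only combine groups from the same module group")
        mg = mgs.pop()
        members = sorted({m for i in ids for m in by_id[i].members})
        out = [g for g in out if g.group_id not in ids]
        out.append(CellTypeGroup(f"Dendrogram_{mg}.group_combined_{k}", mg, members))
    return out


def cell_type_group_scores(groups: list[CellTypeGroup],
                           subgroup_scores: pd.DataFrame) -> pd.DataFrame:
    """Per-sample cell-type-group score: mean of z-scored member subgroup scores."""
    out = {}
    for g in groups:
        missing = [m for m in g.members if m not in subgroup_scores.columns]
        if missing:
            raise KeyError(f"group {g.group_id} members missing from subgroup scores: {missing}")
        block = subgroup_scores[g.members].values.astype(float)
        sd = block.std(axis=0)
        sd[sd == 0] = 1.0
        z = (block - block.mean(axis=0)) / sd
        out[g.group_id] = z.mean(axis=1)
    return pd.DataFrame(out, index=subgroup_scores.index)
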
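"""Cohort-level profiling: immune scores, patient clustering and projection
of a fitted model into an independent cohort."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.metrics import silhouette_score

from .activity import tf_activity_ulm
from .deconvolution import build_feature_table, marker_enrichment
from .grouping import FeatureSubgroup, subgroup_scores
from .integration import CellTypeGroup, cell_type_group_scores
from .io import FittedModelBundle, GeneSetCollection, logger
from .modules import _eigengene


@dataclass
class PatientClustering:
    labels: pd.Series          # sample -> cluster label, contiguous 1..k
    linkage: np.ndarray
    k: int
    features: list[str]


def immune_scores(expr: pd.DataFrame, immune_sets: GeneSetCollection,
                  min_genes: int = 3) -> pd.DataFrame:
    """Per-sample immune response scores: mean of member genes' cohort
    z-scored expression, one column per gene set."""
    return marker_enrichment(expr, immune_sets, min_genes=min_genes)


def immune_classes(scores: pd.DataFrame) -> pd.Series:
    """Hot / intermediate / cold tumor classes as within-cohort tertiles of
    the mean immune score."""
    mean = scores.mean(axis=1)
    lo, hi = np.quantile(mean.values, [1 / 3, 2 / 3])
    labels = np.where(mean <= lo, "cold", np.where(mean <= hi, "intermediate", "hot"))
    return pd.Series(labels, index=scores.index, name="immune_class")


def cluster_patients(features: pd.DataFrame, k: int | str = "auto",
                     max_k: int = 6) -> PatientClustering:
    """Ward hierarchical clustering of samples on z-scored features.

    ``k='auto'`` picks the number of clusters by maximum average silhouette
    over 2..max_k. Cluster labels are renumbered contiguously in dendrogram
    leaf order so the output is deterministic.
    """
    n = features.shape[0]
    if isinstance(k, int) and k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    sd = features.std(axis=0, ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        logger.warning("dropping constant feature columns: %s", constant)
        features = features.drop(columns=constant)
        sd = sd.drop(constant)
    X = (features - features.mean(axis=0)) / sd
    Z = sch.linkage(X.values, method="ward")
    if k == "auto":
        best_k, best_sil = 2, -np.inf
        for kk in range(2, min(max_k, n - 1) + 1):
            labels = sch.fcluster(Z, t=kk, criterion="maxclust")
            if len(set(labels)) < 2:
                continue
            sil = silhouette_score(X.values, labels)
            if sil > best_sil:
                best_k, best_sil = kk, sil
        k = best_k
    raw = sch.fcluster(Z, t=k, criterion="maxclust")
    order = sch.leaves_list(Z)
    remap: dict[int, int] = {}
    for leaf in order:
        lab = int(raw[leaf])
        if lab not in remap:
            remap[lab] = len(remap) + 1
    labels = pd.Series([remap[int(v)] for v in raw], index=features.index, name="cluster")
    return PatientClustering(labels=labels, linkage=Z, k=int(k), features=list(features.columns))


def project_cohort(
    bundle: FittedModelBundle,
    new_expr: pd.DataFrame,
    signatures: dict[str, pd.DataFrame],
    regulons: pd.DataFrame,
    allow_missing: bool = False,
    min_targets: int = 5,
) -> dict[str, pd.DataFrame]:
    """Project a fitted model into an independent cohort.

    Deconvolution features are recomputed on the new cohort with the fitted
    engine grid and subgroup scores are rebuilt from the stored memberships
    (z-scoring within the new cohort). TF activities are re-inferred and
    each module eigengene recomputed on the stored members, re-oriented by
    the positive-mean rule — the modules are identified afresh from the new
    cohort's expression rather than transferred as frozen loadings. Cell
    type group scores follow from the stored group memberships.
    """
    table, _ = build_feature_table(new_expr, bundle.engines, signatures)
    sgs = []
    for sg in bundle.subgroups:
        members = [m for m in sg["members"] if m in table.columns]
        missing = sorted(set(sg["members"]) - set(members))
        if missing and not allow_missing:
            raise KeyError(
                f"subgroup {sg['subgroup_id']} members missing in new cohort: {missing}")
        if missing:
            logger.warning("subgroup %s: computing score without missing members %s",
                           sg["subgroup_id"], missing)
        if not members:
            raise KeyError(f"subgroup {sg['subgroup_id']} has no members in the new cohort")
        sgs.append(FeatureSubgroup(sg["subgroup_id"], sg["cell_type"], members))
    sg_scores = subgroup_scores(sgs, table)

    activity = tf_activity_ulm(new_expr, regulons, min_targets=min_targets)
    eigs = {}
    for label, members in bundle.modules.items():
        present = [tf for tf in members if tf in activity.index]
        missing = sorted(set(members) - set(present))
        if missing and not allow_missing:
            raise KeyError(f"module {label} TFs missing in new cohort: {missing}")
        if missing:
            logger.warning("module %s: eigengene computed without missing TFs %s", label, missing)
        if len(present) < 2:
            raise KeyError(f"module {label} has < 2 TFs available in the new cohort")
        eigs[label] = _eigengene(activity.loc[present])
    eig_df = pd.DataFrame(eigs, index=new_expr.columns)

    groups = [CellTypeGroup(g["group_id"], g["module_group"], list(g["members"]))
              for g in bundle.cell_type_groups]
    group_scores = cell_type_group_scores(groups, sg_scores)
    return {
        "subgroup_scores": sg_scores,
        "module_scores": eig_df,
        "group_scores": group_scores,
        "tf_activity": activity,
        "feature_table": table,
    }
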
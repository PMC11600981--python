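"""Weighted TF co-activity network analysis (WTCNA).

The weighted-coexpression workflow applied to inferred TF activities rather
than expression: soft-thresholded unsigned adjacency a_ij = |cor|^beta,
topological-overlap similarity, average-linkage clustering on 1 - TOM with
a static tree cut, color-named modules, eigengene scores and kME module
membership, hub selection, pathway-correlation grouping of modules and
over-representation analysis of hub targets.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .io import logger

# WGCNA's conventional color sequence; modules are named by decreasing size.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
)
GREY = "grey"


def coactivity_adjacency(tf_activity: pd.DataFrame, beta: float = 6.0) -> pd.DataFrame:
    """Unsigned soft-thresholded adjacency |Pearson|^beta with zero diagonal."""
    if tf_activity.shape[1] < 3:
        raise ValueError("need >= 3 samples to build a co-activity network")
    if beta < 1:
        raise ValueError("soft power beta must be >= 1")
    sd = tf_activity.std(axis=1, ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant activity rows: {constant}")
    r = np.corrcoef(tf_activity.values)
    a = np.abs(r) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=tf_activity.index, columns=tf_activity.index)


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap matrix; TOM(i,i) = 1."""
    A = adjacency.values
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T):
        raise ValueError("adjacency must be square and symmetric")
    L = A @ A
    k = A.sum(axis=0)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + A) / (kmin + 1.0 - A)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(
    adjacency: pd.DataFrame,
    min_module_size: int = 5,
    cut_quantile: float = 0.90,
    tf_activity: pd.DataFrame | None = None,
    eigengene_merge_cor: float = 0.8,
) -> dict[str, list[str]]:
    """Detect color-named TF modules from the co-activity adjacency.

    Average-linkage clustering on 1 - TOM with a static cut at the
    ``cut_quantile`` quantile of merge heights; clusters below
    ``min_module_size`` fall into "grey". If ``tf_activity`` is supplied,
    modules whose eigengenes correlate >= ``eigengene_merge_cor`` are merged
    afterwards. Modules are named by decreasing size.
    """
    tfs = list(adjacency.index)
    if len(tfs) < min_module_size:
        logger.warning("fewer TFs (%d) than min_module_size (%d); all grey", len(tfs), min_module_size)
        return {GREY: tfs}
    if adjacency.values.max() == 0:
        logger.warning("adjacency is all zero; no modules detectable, all TFs grey")
        return {GREY: tfs}
    tom = tom_similarity(adjacency)
    dist = 1.0 - tom.values
    np.fill_diagonal(dist, 0.0)
    Z = sch.linkage(ssd.squareform(dist, checks=False), method="average")
    cut = float(np.quantile(Z[:, 2], cut_quantile))
    labels = sch.fcluster(Z, t=cut, criterion="distance")

    clusters: dict[int, list[str]] = {}
    for tf, lab in zip(tfs, labels):
        clusters.setdefault(int(lab), []).append(tf)
    grey: list[str] = []
    members_list = []
    for lab, members in clusters.items():
        if len(members) >= min_module_size:
            members_list.append(sorted(members))
        else:
            grey.extend(members)

    if tf_activity is not None and len(members_list) > 1:
        members_list = _merge_by_eigengene(members_list, tf_activity, eigengene_merge_cor)

    members_list.sort(key=lambda m: (-len(m), m[0]))
    modules = {MODULE_COLORS[i]: m for i, m in enumerate(members_list)}
    if grey:
        modules[GREY] = sorted(grey)
    return modules


def _merge_by_eigengene(members_list: list[list[str]], tf_activity: pd.DataFrame,
                        threshold: float) -> list[list[str]]:
    while len(members_list) > 1:
        eigs = [_eigengene(tf_activity.loc[m]) for m in members_list]
        best = None
        for i, j in itertools.combinations(range(len(members_list)), 2):
            r = float(np.corrcoef(eigs[i], eigs[j])[0, 1])
            if r >= threshold and (best is None or r > best[0]):
                best = (r, i, j)
        if best is None:
            break
        _, i, j = best
        merged = sorted(members_list[i] + members_list[j])
        members_list = [m for k, m in enumerate(members_list) if k not in (i, j)] + [merged]
        logger.info("merged two modules with eigengene correlation >= %.2f", threshold)
    return members_list


def _eigengene(member_activity: pd.DataFrame) -> np.ndarray:
    """First principal component across samples of standardized member
    activities, oriented positively with the mean member activity, scaled to
    unit variance."""
    X = member_activity.values.astype(float)           # members x samples
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Xz = (X - X.mean(axis=1, keepdims=True)) / sd
    u, s, vt = np.linalg.svd(Xz, full_matrices=False)
    pc1 = vt[0] * s[0]
    mean_act = Xz.mean(axis=0)
    if np.corrcoef(pc1, mean_act)[0, 1] < 0:
        pc1 = -pc1
    sdev = pc1.std()
    return pc1 / sdev if sdev > 0 else pc1


def module_scores(modules: dict[str, list[str]], tf_activity: pd.DataFrame
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Eigengene per non-grey module and kME of every TF against every module.

    kME(TF, M) is the Pearson correlation of the TF's activity with module
    M's eigengene, the standard module-membership measure.
    """
    eigs = {}
    for label, members in modules.items():
        if label == GREY:
            continue
        if len(members) < 2:
            raise ValueError(f"module {label} has < 2 members")
        eigs[label] = _eigengene(tf_activity.loc[members])
    eig_df = pd.DataFrame(eigs, index=tf_activity.columns)
    act = tf_activity.values
    act_sd = act.std(axis=1)
    kme = {}
    for label in eig_df.columns:
        e = eig_df[label].values
        ec = e - e.mean()
        cov = (act - act.mean(axis=1, keepdims=True)) @ ec / act.shape[1]
        with np.errstate(invalid="ignore", divide="ignore"):
            kme[label] = cov / (act_sd * ec.std())
    kme_df = pd.DataFrame(kme, index=tf_activity.index)
    return eig_df, kme_df


def module_orientation_signs(modules: dict[str, list[str]], tf_activity: pd.DataFrame) -> dict[str, int]:
    """Sign applied to PC1 by the positive-mean orientation rule, per module
    (recorded in the fitted bundle for provenance)."""
    signs = {}
    for label, members in modules.items():
        if label == GREY:
            continue
        X = tf_activity.loc[members].values.astype(float)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        Xz = (X - X.mean(axis=1, keepdims=True)) / sd
        _, s, vt = np.linalg.svd(Xz, full_matrices=False)
        pc1 = vt[0] * s[0]
        signs[label] = -1 if np.corrcoef(pc1, Xz.mean(axis=0))[0, 1] < 0 else 1
    return signs


def select_hubs(
    modules: dict[str, list[str]],
    kme: pd.DataFrame,
    adjacency: pd.DataFrame,
    kme_threshold: float = 0.8,
    degree_quantile: float = 0.9,
    degree_scope: str = "global",
) -> dict[str, list[str]]:
    """Hub TFs: kME above threshold AND weighted degree in the top decile.

    Degree is whole-network weighted connectivity (adjacency row sums); with
    ``degree_scope='module'`` the degree quantile is taken within each
    module instead. Modules may legitimately end up with no hubs.
    """
    degrees = adjacency.sum(axis=1)
    global_thr = float(np.quantile(degrees.values, degree_quantile))
    hubs = {}
    for label, members in modules.items():
        if label == GREY:
            continue
        thr = global_thr if degree_scope == "global" else float(
            np.quantile(degrees.loc[members].values, degree_quantile))
        hubs[label] = sorted(
            tf for tf in members
            if kme.loc[tf, label] > kme_threshold and degrees[tf] >= thr
        )
        if not hubs[label]:
            logger.info("no hub TFs found for module %s", label)
    return hubs


def module_pathway_grouping(
    eigengenes: pd.DataFrame,
    pathway_activity: pd.DataFrame,
    alpha: float = 0.05,
    max_k: int = 5,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Correlate module eigengenes with pathway activities and group modules.

    Returns a long-format correlation table (module, pathway, r, p,
    significant) and module groups obtained by PCA of the module x pathway
    correlation matrix (first two PCs), Ward clustering, and silhouette-based
    choice of k in 2..min(max_k, m-1). Group ids concatenate member colors.
    """
    shared = eigengenes.index.intersection(pathway_activity.columns)
    if len(shared) < 5:
        raise ValueError("need >= 5 shared samples for module-pathway correlation")
    mods = list(eigengenes.columns)
    paths = list(pathway_activity.index)
    rows = []
    C = np.zeros((len(mods), len(paths)))
    for i, m in enumerate(mods):
        for j, pw in enumerate(paths):
            r, p = scipy.stats.pearsonr(eigengenes.loc[shared, m], pathway_activity.loc[pw, shared])
            C[i, j] = r
            rows.append({"module": m, "pathway": pw, "r": r, "p": p, "significant": p < alpha})
    table = pd.DataFrame(rows)

    if len(mods) < 3:
        gid = "_".join(mods)
        return table, {gid: mods}

    Cc = C - C.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(Cc, full_matrices=False)
    coords = Cc @ vt[: min(2, vt.shape[0])].T
    Z = sch.linkage(coords, method="ward")
    best_k, best_sil = 2, -np.inf
    for k in range(2, min(max_k, len(mods) - 1) + 1):
        labels = sch.fcluster(Z, t=k, criterion="maxclust")
        if len(set(labels)) < 2:
            continue
        sil = silhouette_score(coords, labels)
        if sil > best_sil:
            best_k, best_sil = k, sil
    labels = sch.fcluster(Z, t=best_k, criterion="maxclust")
    groups: dict[str, list[str]] = {}
    for lab in sorted(set(labels)):
        members = [mods[i] for i in range(len(mods)) if labels[i] == lab]
        groups["_".join(members)] = members
    return table, groups


def hypergeom_ora_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric p for drawing >= k set members in a list of
    size n from a universe of N containing K set members."""
    if k > min(n, K):
        raise ValueError("overlap cannot exceed list or set size")
    return float(scipy.stats.hypergeom.sf(k - 1, N, K, n))


def hub_target_ora(
    hubs: dict[str, list[str]],
    regulons: pd.DataFrame,
    expr: pd.DataFrame,
    gene_sets,
    variability_quantile: float = 0.8,
) -> pd.DataFrame:
    """Over-representation of gene sets in each module's hub-TF target list.

    Per module: hub targets are restricted to the universe (expressed genes
    appearing in the regulon network), targets claimed by more than one
    module are dropped, and only the top (1 - variability_quantile) fraction
    by expression variance is kept. p-values are upper-tail hypergeometric,
    BH-adjusted across gene sets within each module.
    """
    if not any(hubs.values()):
        raise ValueError("no module has hub TFs")
    net_genes = set(regulons["source"]) | set(regulons["target"])
    universe = [g for g in expr.index if g in net_genes]
    uset = set(universe)
    variances = expr.loc[universe].var(axis=1)

    raw_lists = {}
    for label, tf_list in hubs.items():
        tgts = set(regulons[regulons["source"].isin(tf_list)]["target"]) & uset
        raw_lists[label] = tgts
    counts: dict[str, int] = {}
    for tgts in raw_lists.values():
        for g in tgts:
            counts[g] = counts.get(g, 0) + 1

    rows = []
    for label in sorted(raw_lists):
        unique = sorted(g for g in raw_lists[label] if counts[g] == 1)
        if not unique:
            logger.warning("module %s: no unique hub targets; skipped", label)
            continue
        v = variances.loc[unique]
        thr = float(np.quantile(v.values, variability_quantile))
        chosen = sorted(v[v >= thr].index)
        if not chosen:
            logger.warning("module %s: no targets pass the variability filter; skipped", label)
            continue
        n = len(chosen)
        N = len(universe)
        mod_rows = []
        for name, genes in gene_sets.items():
            K = len(set(genes) & uset)
            k = len(set(genes) & set(chosen))
            p = hypergeom_ora_p(k, n, K, N) if K else 1.0
            mod_rows.append({"module": label, "gene_set": name, "k": k, "K": K,
                             "n": n, "N": N, "p": p})
        ps = [r["p"] for r in mod_rows]
        _, q, _, _ = multipletests(ps, method="fdr_bh")
        for r, qv in zip(mod_rows, q):
            r["q"] = float(qv)
        rows.extend(mod_rows)
    return pd.DataFrame(rows)
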
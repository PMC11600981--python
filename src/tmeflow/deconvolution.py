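"""Deconvolution feature generation.

Two transparent engines produce the engine x signature grid of cell-type
features from bulk expression:

* ``nnls`` — reference-based non-negative least squares on linear-scale
  expression (mixing is linear in TPM space), fractions normalized to sum 1;
* ``marker_enrichment`` — mean of within-cohort z-scored expression over a
  cell type's marker genes, computed on the log2 scale.

An import path wraps externally computed feature matrices (engine label
``external``) so published deconvolution outputs can enter the pipeline
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

from .io import GeneSetCollection, logger

ENGINES = ("nnls", "marker_enrichment")


@dataclass(frozen=True)
class DeconvFeature:
    feature_id: str
    engine: str
    signature_name: str
    cell_type: str
    subtype_label: str | None = None


def make_feature_id(engine: str, signature: str, cell_type: str) -> str:
    return f"{engine}_{signature}_{cell_type}"


def to_linear(expr: pd.DataFrame) -> pd.DataFrame:
    """Undo the log2(TPM+1) transform."""
    return np.exp2(expr) - 1.0


def nnls_fractions(expr: pd.DataFrame, signature: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample NNLS cell-type fractions.

    Solves min ||S f - b||^2 s.t. f >= 0 on linear-scale expression over the
    shared genes, then normalizes f to sum 1. Samples whose solution is all
    zero are flagged and reported as uniform fractions so downstream
    correlation code always sees finite values.

    Returns (samples x cell-types fractions, boolean zero-solution flags).
    """
    shared = signature.index.intersection(expr.index)
    if len(shared) == 0:
        raise ValueError("no genes shared between expression matrix and signature")
    S = signature.loc[shared]
    per_type = (S != 0).sum(axis=0)
    thin = per_type[per_type < 2].index.tolist()
    if thin:
        raise ValueError(f"cell types with < 2 shared signature genes: {thin}")
    Sv = S.values.astype(float)
    rank = np.linalg.matrix_rank(Sv)
    degenerate = rank < Sv.shape[1]
    if degenerate:
        logger.warning("signature is rank-deficient (rank %d < %d columns); "
                       "falling back to clipped pseudo-inverse solutions", rank, Sv.shape[1])
        pinv = np.linalg.pinv(Sv)
    B = to_linear(expr.loc[shared]).values
    n_types = Sv.shape[1]
    out = np.empty((expr.shape[1], n_types))
    flags = np.zeros(expr.shape[1], dtype=bool)
    for j in range(expr.shape[1]):
        if degenerate:
            f = np.clip(pinv @ B[:, j], 0.0, None)
        else:
            f, _ = scipy.optimize.nnls(Sv, B[:, j])
        total = f.sum()
        if total <= 0:
            flags[j] = True
            out[j] = 1.0 / n_types
        else:
            out[j] = f / total
    if flags.any():
        logger.warning("%d samples had all-zero NNLS solutions; reported as uniform fractions",
                       int(flags.sum()))
    frac = pd.DataFrame(out, index=expr.columns, columns=signature.columns)
    return frac, pd.Series(flags, index=expr.columns, name="zero_solution")


def cohort_zscores(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores across the cohort; constant genes map to NaN."""
    mu = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=0)
    z = expr.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z


def marker_enrichment(expr: pd.DataFrame, marker_sets: GeneSetCollection,
                      min_genes: int = 3) -> pd.DataFrame:
    """Mean of member genes' within-cohort z-scored expression, per sample.

    Sets intersecting fewer than ``min_genes`` usable (measured, non-constant)
    genes are dropped with a warning. Duplicate genes inside a set count once.
    """
    z = cohort_zscores(expr)
    usable = z.dropna(axis=0).index
    scores = {}
    for name, genes in marker_sets.items():
        members = pd.Index(pd.unique(pd.Series(genes))).intersection(usable)
        if len(members) < min_genes:
            logger.warning("marker set %s has %d usable genes (< %d); dropped",
                           name, len(members), min_genes)
            continue
        scores[name] = z.loc[members].mean(axis=0)
    return pd.DataFrame(scores, index=expr.columns)


def markers_from_signature(signature: pd.DataFrame, n_top: int = 25) -> GeneSetCollection:
    """Derive per-cell-type marker sets from a signature matrix.

    Markers are the ``n_top`` genes with the highest specificity ratio
    (expression in the type over the mean across all types).
    """
    eps = 1e-12
    row_mean = signature.mean(axis=1)
    sets = {}
    for ct in signature.columns:
        specificity = signature[ct] / (row_mean + eps)
        sets[ct] = specificity.sort_values(ascending=False).head(n_top).index.tolist()
    return GeneSetCollection(sets, {ct: "derived from signature" for ct in signature.columns})


def build_feature_table(
    expr: pd.DataFrame,
    engines: list[str],
    signatures: dict[str, pd.DataFrame],
    markers_per_signature: int = 25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Engine x signature x cell-type feature grid.

    Returns (samples x features table, feature metadata table). Column order
    is deterministic: engine, then signature, then cell type, lexicographic.
    """
    if not engines:
        raise ValueError("at least one engine required")
    if not signatures:
        raise ValueError("at least one signature required")
    unknown = set(engines) - set(ENGINES)
    if unknown:
        raise ValueError(f"unknown engines {sorted(unknown)}; available: {ENGINES}")
    columns: dict[str, pd.Series] = {}
    meta: list[DeconvFeature] = []
    for engine in sorted(engines):
        for sig_name in sorted(signatures):
            sig = signatures[sig_name]
            if engine == "nnls":
                values, _ = nnls_fractions(expr, sig)
            else:
                sets = markers_from_signature(sig, n_top=markers_per_signature)
                values = marker_enrichment(expr, sets)
            for ct in sorted(values.columns):
                fid = make_feature_id(engine, sig_name, ct)
                if fid in columns:
                    raise ValueError(f"feature id collision: {fid}")
                columns[fid] = values[ct]
                meta.append(DeconvFeature(fid, engine, sig_name, ct))
    table = pd.DataFrame(columns, index=expr.columns)
    meta_df = pd.DataFrame([vars(m) for m in meta]).set_index("feature_id")
    return table, meta_df


def import_feature_table(table: pd.DataFrame, metadata: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wrap an externally computed feature matrix with user metadata.

    ``metadata`` must carry a ``cell_type`` column indexed by feature id;
    the engine label is set to ``external``.
    """
    missing = set(table.columns) - set(metadata.index)
    if missing:
        raise ValueError(f"metadata missing for imported features: {sorted(missing)[:5]}")
    if "cell_type" not in metadata.columns:
        raise ValueError("imported metadata must have a cell_type column")
    meta = metadata.loc[list(table.columns)].copy()
    meta["engine"] = "external"
    if "signature_name" not in meta.columns:
        meta["signature_name"] = "external"
    if "subtype_label" not in meta.columns:
        meta["subtype_label"] = None
    if not np.isfinite(table.values).all():
        raise ValueError("imported feature table contains non-finite values")
    return table.copy(), meta[["engine", "signature_name", "cell_type", "subtype_label"]]
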
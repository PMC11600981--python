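"""Synthetic cohort generator.

Produces a fully specified cohort — expression, cell-type signature,
marker/immune gene sets, a signed regulon network, pathway footprint
weights, survival — together with the ground truth that generated it, so
every downstream stage can be scored offline.

Generative model
----------------
* Cell-type fractions are Dirichlet draws on the simplex. Samples belong to
  one of two patient landscapes that differ along a "dual NK" axis: the
  landscape-1 concentration is raised for the first (resting-NK-like) cell
  type and lowered for the second (active-NK-like) one, and vice versa.
* Bulk expression is the linear mixture signature @ fractions, perturbed
  element-wise by lognormal noise, then log2(1 + .) transformed.
* TF activities are planted as module scores (one per TF module, tracking
  the fraction of a dedicated cell type) plus TF-level noise; every TF
  shifts its regulon targets on the log2 scale by weight x activity.
* Survival times are exponential with log-hazard proportional to the
  planted "dual NK" group score (resting minus active fraction, z-scored),
  censored administratively at a fixed horizon plus uniform dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    GeneSetCollection,
    PipelineConfig,
    child_seed,
    logger,
    validate_expression,
    write_expression,
    write_gmt,
    write_pathway_weights,
    write_regulons,
    write_signature,
    write_survival,
)

DEFAULT_CELL_TYPES = (
    "NK_resting", "NK_active", "Tcell", "Bcell",
    "Macrophage", "Dendritic", "Fibroblast", "Cancer",
)

# PROGENy-style names for the common core of 14 signaling pathways; the
# first four track the planted TF modules.
PATHWAY_NAMES = (
    "JAK-STAT", "NFkB", "MAPK", "TGFb", "TNFa", "Androgen", "EGFR",
    "Estrogen", "Hypoxia", "PI3K", "Trail", "VEGF", "WNT", "p53",
)


@dataclass
class SyntheticTruth:
    cell_fractions: pd.DataFrame            # samples x cell types, rows sum to 1
    tf_module_assignment: pd.Series         # TF -> module label ("none" if unassigned)
    planted_module_activity: pd.DataFrame   # modules x samples
    patient_landscape: pd.Series            # sample -> 1 or 2
    planted_group_score: pd.Series          # z-scored dual-NK axis per sample
    hazard_beta: float
    seed: int

    def __post_init__(self) -> None:
        sums = self.cell_fractions.sum(axis=1).values
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("cell fraction rows must sum to 1")


@dataclass
class SyntheticCohort:
    expression: pd.DataFrame
    signatures: dict[str, pd.DataFrame]
    marker_sets: GeneSetCollection
    regulons: pd.DataFrame
    pathway_model: pd.DataFrame
    immune_sets: GeneSetCollection
    survival: pd.DataFrame
    truth: SyntheticTruth


def generate_cohort(
    n_samples: int = 120,
    n_genes: int = 2000,
    cell_types=DEFAULT_CELL_TYPES,
    config: PipelineConfig | None = None,
    n_tfs: int = 60,
    n_modules: int = 4,
    targets_per_tf: int = 15,
    markers_per_type: int = 40,
    noise_sigma: float = 0.2,
    tf_effect: float = 0.8,
    module_noise: float = 0.5,
    hazard_beta: float = 1.0,
    baseline_median_days: float = 1000.0,
    censor_horizon_days: float = 1825.0,
    seed: int | None = None,
) -> SyntheticCohort:
    """Generate a cohort with the statistical structure the pipeline assumes.

    Parameters mirror the study conditions at desk scale: 120 samples,
    2,000 genes, 8 cell types and 60 TFs in 4 planted modules by default.
    ``noise_sigma`` is the standard deviation of the lognormal measurement
    noise on the natural-log scale; ``tf_effect`` scales the log2 shift a
    unit of TF activity adds to each target; ``module_noise`` is the
    TF-level noise around the shared module score (0.5 gives within-module
    activity correlations of ~0.8).
    """
    config = config or PipelineConfig()
    cell_types = list(cell_types)
    root = int(config.rng_seed if seed is None else seed)

    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    if len(cell_types) < 3:
        raise ValueError("need at least 3 cell types")
    if n_genes < 50 * len(cell_types):
        raise ValueError(f"n_genes must be >= {50 * len(cell_types)} for {len(cell_types)} cell types")
    if n_genes < markers_per_type * len(cell_types) + n_tfs * targets_per_tf:
        raise ValueError("not enough genes for the requested markers and regulon targets")
    if n_modules > n_tfs or n_modules > len(cell_types):
        raise ValueError("n_modules must not exceed n_tfs or the number of cell types")

    rng = {name: np.random.default_rng(child_seed(root, f"synthetic/{name}"))
           for name in ("landscape", "fractions", "signature", "noise",
                        "regulons", "activity", "pathways", "survival")}

    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"S{i:04d}" for i in range(n_samples)]
    tfs = [f"TF{i:03d}" for i in range(n_tfs)]

    # --- patient landscapes and Dirichlet fractions -----------------------
    landscape = np.ones(n_samples, dtype=int)
    landscape[rng["landscape"].permutation(n_samples)[: n_samples // 2]] = 2
    alpha = np.full((n_samples, len(cell_types)), 2.0)
    alpha[landscape == 1, 0] = 8.0   # resting-NK-like enriched in landscape 1
    alpha[landscape == 1, 1] = 0.8
    alpha[landscape == 2, 0] = 0.8
    alpha[landscape == 2, 1] = 8.0   # active-NK-like enriched in landscape 2
    fractions = np.vstack([rng["fractions"].dirichlet(a) for a in alpha])
    frac_df = pd.DataFrame(fractions, index=samples, columns=cell_types)

    # --- signature matrix and markers -------------------------------------
    baseline = rng["signature"].lognormal(mean=np.log(10.0), sigma=0.6, size=n_genes)
    S = np.tile(baseline[:, None], (1, len(cell_types)))
    marker_sets: dict[str, list[str]] = {}
    pos = 0
    for j, ct in enumerate(cell_types):
        idx = np.arange(pos, pos + markers_per_type)
        boost = rng["signature"].uniform(20.0, 40.0, size=markers_per_type)
        S[idx, j] *= boost
        marker_sets[f"markers_{ct}"] = [genes[i] for i in idx]
        pos += markers_per_type
    sig_df = pd.DataFrame(S, index=genes, columns=cell_types)

    # --- regulons: unique targets per TF, signed weights -------------------
    target_pool = np.arange(pos, pos + n_tfs * targets_per_tf)
    edges = []
    module_of = {}
    for t, tf in enumerate(tfs):
        module_of[tf] = f"M{t % n_modules + 1}" if n_modules else "none"
        tgt_idx = target_pool[t * targets_per_tf:(t + 1) * targets_per_tf]
        signs = np.where(rng["regulons"].random(targets_per_tf) < 0.75, 1.0, -1.0)
        for g, s in zip(tgt_idx, signs):
            edges.append((tf, genes[g], float(s)))
    regulons = pd.DataFrame(edges, columns=["source", "target", "weight"])

    # --- planted module scores and TF activities ---------------------------
    module_labels = [f"M{j + 1}" for j in range(n_modules)]
    zf = (fractions - fractions.mean(0)) / fractions.std(0)
    module_activity = np.vstack([zf[:, j] for j in range(n_modules)])  # modules x samples
    tf_activity = np.zeros((n_tfs, n_samples))
    for t, tf in enumerate(tfs):
        j = t % n_modules
        tf_activity[t] = module_activity[j] + module_noise * rng["activity"].standard_normal(n_samples)

    # --- expression: mixture + lognormal noise + TF target shifts ----------
    mixture = S @ fractions.T
    lognoise = np.exp(noise_sigma * rng["noise"].standard_normal(mixture.shape))
    expr = np.log2(1.0 + mixture * lognoise)
    gene_index = {g: i for i, g in enumerate(genes)}
    for t, tf in enumerate(tfs):
        sub = regulons[regulons["source"] == tf]
        rows = [gene_index[g] for g in sub["target"]]
        w = sub["weight"].values[:, None]
        expr[rows, :] += tf_effect * w * tf_activity[t][None, :]
    np.clip(expr, 0.0, None, out=expr)
    expr_df = validate_expression(pd.DataFrame(expr, index=genes, columns=samples))

    # --- pathway footprint weights -----------------------------------------
    n_pathways = len(PATHWAY_NAMES)
    W = np.zeros((n_genes, n_pathways))
    for j in range(n_modules):
        member_tfs = [tfs[t] for t in range(n_tfs) if t % n_modules == j]
        tgts = regulons[regulons["source"].isin(member_tfs)]
        for g, w in zip(tgts["target"], tgts["weight"]):
            W[gene_index[g], j] = w * tf_effect
    bg = np.arange(pos + n_tfs * targets_per_tf, n_genes)
    for j in range(n_modules, n_pathways):
        foot = rng["pathways"].choice(bg, size=min(30, len(bg)), replace=False)
        W[foot, j] = rng["pathways"].normal(0.0, 0.5, size=len(foot))
    pathway_df = pd.DataFrame(W, index=genes, columns=list(PATHWAY_NAMES))

    # --- immune response gene sets ------------------------------------------
    immune = GeneSetCollection(
        {
            "cytotoxicity": marker_sets[f"markers_{cell_types[1]}"][:20]
            + marker_sets[f"markers_{cell_types[2]}"][:10],
            "immune_infiltrate": [g for ct in cell_types[:6] for g in marker_sets[f"markers_{ct}"][:8]],
            "antigen_presentation": marker_sets[f"markers_{cell_types[5 % len(cell_types)]}"][:15],
        },
        {"cytotoxicity": "synthetic cytotoxic program",
         "immune_infiltrate": "synthetic pan-immune infiltration set",
         "antigen_presentation": "synthetic APC program"},
    )

    # --- survival -----------------------------------------------------------
    axis = fractions[:, 0] - fractions[:, 1]
    score = (axis - axis.mean()) / axis.std()
    lam0 = np.log(2.0) / baseline_median_days
    T = rng["survival"].exponential(1.0, size=n_samples) / (lam0 * np.exp(hazard_beta * score))
    dropout = rng["survival"].uniform(0.0, 3.0 * censor_horizon_days, size=n_samples)
    C = np.minimum(censor_horizon_days, dropout)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    surv_df = pd.DataFrame({"time_days": time, "event": event}, index=pd.Index(samples, name="sample"))

    truth = SyntheticTruth(
        cell_fractions=frac_df,
        tf_module_assignment=pd.Series(module_of, name="module").rename_axis("tf"),
        planted_module_activity=pd.DataFrame(module_activity, index=module_labels, columns=samples),
        patient_landscape=pd.Series(landscape, index=samples, name="landscape").rename_axis("sample"),
        planted_group_score=pd.Series(score, index=samples, name="dual_nk_score").rename_axis("sample"),
        hazard_beta=float(hazard_beta),
        seed=root,
    )
    return SyntheticCohort(
        expression=expr_df,
        signatures={"synthsig": sig_df},
        marker_sets=GeneSetCollection(marker_sets, {k: "synthetic marker set" for k in marker_sets}),
        regulons=regulons,
        pathway_model=pathway_df,
        immune_sets=immune,
        survival=surv_df,
        truth=truth,
    )


def truth_report(cohort: SyntheticCohort) -> dict[str, pd.DataFrame]:
    """Tables of planted parameters sufficient to score recovery."""
    t = cohort.truth
    return {
        "cell_fractions": t.cell_fractions,
        "tf_modules": t.tf_module_assignment.to_frame(),
        "module_activity": t.planted_module_activity,
        "patient_landscape": t.patient_landscape.to_frame(),
        "group_score": t.planted_group_score.to_frame(),
        "hazard": pd.DataFrame({"hazard_beta": [t.hazard_beta], "seed": [t.seed]}),
    }


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write every cohort file in the formats the readers accept, plus truth/."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(cohort.expression, out / "expression.tsv")
    for name, sig in cohort.signatures.items():
        write_signature(sig, out / f"signature_{name}.tsv")
    write_gmt(cohort.marker_sets, out / "marker_sets.gmt")
    write_regulons(cohort.regulons, out / "regulons.tsv")
    write_pathway_weights(cohort.pathway_model, out / "pathway_weights.tsv")
    write_gmt(cohort.immune_sets, out / "immune_sets.gmt")
    write_survival(cohort.survival, out / "survival.tsv")
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    for name, table in truth_report(cohort).items():
        table.to_csv(truth_dir / f"{name}.tsv", sep="\t")
    logger.info("wrote synthetic cohort to %s", out)
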
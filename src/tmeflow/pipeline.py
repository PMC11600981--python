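"""End-to-end orchestration.

``run_fit`` executes the discovery flow on a training cohort —
deconvolution grid, feature filtering and merging, TF and pathway activity
inference, TF module detection and pathway grouping, integration into cell
type groups, unsupervised patient clustering, and consensus shadow-feature
selection with the patient clusters as labels — and returns a fitted-model
bundle plus a run manifest. ``run_validate`` projects a bundle into an
independent cohort, re-clusters the projected samples, fits Cox models on
the selected cell-type-group scores, stratifies risk and reports
Kaplan-Meier / log-rank results. Selection labels come from unsupervised
patient clusters, never from survival, so discovery stays separate from
outcome.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .activity import pathway_activity_mlm, tf_activity_ulm
from .boruta import consensus_select
from .deconvolution import ENGINES, build_feature_table
from .grouping import filter_features, merge_correlated_features
from .integration import (build_cell_type_groups, cell_type_group_scores,
                          correlate_subgroups_modules)
from .io import (FittedModelBundle, GeneSetCollection, PipelineConfig,
                 filter_regulons, logger, save_bundle)
from .modules import (coactivity_adjacency, detect_modules, module_orientation_signs,
                      module_pathway_grouping, module_scores, select_hubs)
from .profiling import cluster_patients, immune_scores, project_cohort
from .survival import fit_cox, km_estimate, logrank, stratify


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config: dict
    stages: list[str] = field(default_factory=list)
    seeds: dict[str, int] = field(default_factory=dict)
    input_digests: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    package_version: str = __version__

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


FIT_STAGES = (
    "deconvolve", "filter_merge", "tf_activity", "pathway_activity",
    "modules", "module_pathway_grouping", "integrate", "cluster_patients",
    "consensus_select",
)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, exc) from exc
            return False
    return _Ctx()


def run_fit(
    expr: pd.DataFrame,
    signatures: dict[str, pd.DataFrame],
    regulons: pd.DataFrame,
    pathway_model: pd.DataFrame,
    immune_sets: GeneSetCollection | None,
    config: PipelineConfig,
    engines: list[str] = list(ENGINES),
    n_patient_clusters: int | str = "auto",
) -> tuple[FittedModelBundle, RunManifest, dict]:
    """Fit the full model on a training cohort.

    Returns (bundle, manifest, artifacts); ``artifacts`` holds every
    intermediate table keyed by stage name.
    """
    config.validate()
    manifest = RunManifest(config=config.to_dict())
    art: dict = {}

    with _stage("deconvolve"):
        table, meta = build_feature_table(expr, engines, signatures)
        art["feature_table"], art["feature_meta"] = table, meta

    with _stage("filter_merge"):
        filtered = filter_features(table, config.zero_prop_max, config.min_variance)
        subgroups, sg_scores = merge_correlated_features(
            filtered, meta["cell_type"], config.merge_threshold)
        art["subgroups"], art["subgroup_scores"] = subgroups, sg_scores

    with _stage("tf_activity"):
        reg = filter_regulons(regulons, expr.index)
        activity = tf_activity_ulm(expr, reg)
        art["tf_activity"] = activity

    with _stage("pathway_activity"):
        pw_activity = pathway_activity_mlm(expr, pathway_model)
        art["pathway_activity"] = pw_activity

    with _stage("modules"):
        adjacency = coactivity_adjacency(activity, config.soft_power)
        modules = detect_modules(adjacency, config.min_module_size,
                                 config.cut_quantile, tf_activity=activity)
        eigengenes, kme = module_scores(modules, activity)
        hubs = select_hubs(modules, kme, adjacency,
                           config.kme_threshold, config.degree_quantile)
        art.update(adjacency=adjacency, modules=modules, eigengenes=eigengenes,
                   kme=kme, hubs=hubs)

    with _stage("module_pathway_grouping"):
        mp_table, module_groups = module_pathway_grouping(
            eigengenes, pw_activity, config.significance_alpha)
        art["module_pathway_table"], art["module_groups"] = mp_table, module_groups

    with _stage("integrate"):
        corr, pvals, surviving = correlate_subgroups_modules(
            sg_scores, eigengenes, config.significance_alpha)
        groups = build_cell_type_groups(corr, surviving, module_groups,
                                        config.cut_height, cut_mode=config.cut_mode,
                                        cut_quantile=config.group_cut_quantile)
        group_scores = cell_type_group_scores(groups, sg_scores)
        art.update(subgroup_module_corr=corr, subgroup_module_p=pvals,
                   cell_type_groups=groups, group_scores=group_scores)

    with _stage("cluster_patients"):
        clustering = cluster_patients(group_scores, k=n_patient_clusters)
        art["patient_clusters"] = clustering

    with _stage("consensus_select"):
        consensus = consensus_select(
            group_scores, clustering.labels.values,
            seed=config.child_seed("consensus_select"),
            n_repeats=config.boruta_repeats,
            confirm_frac=config.boruta_confirm_frac,
        )
        art["consensus"] = consensus

    if immune_sets is not None:
        art["immune_scores"] = immune_scores(expr, immune_sets)

    bundle = FittedModelBundle(
        config=config.to_dict(),
        engines=sorted(engines),
        signature_names=sorted(signatures),
        subgroups=[{"subgroup_id": s.subgroup_id, "cell_type": s.cell_type,
                    "members": list(s.members)} for s in subgroups],
        modules={k: list(v) for k, v in modules.items() if k != "grey"},
        module_orientations=module_orientation_signs(modules, activity),
        module_groups={k: list(v) for k, v in module_groups.items()},
        cell_type_groups=[{"group_id": g.group_id, "module_group": g.module_group,
                           "members": list(g.members)} for g in groups],
        selected_features=consensus.selected_features,
        n_patient_clusters=clustering.k,
    )
    manifest.stages = list(FIT_STAGES)
    manifest.seeds = {"consensus_select": config.child_seed("consensus_select")}
    return bundle, manifest, art


def run_validate(
    bundle: FittedModelBundle,
    new_expr: pd.DataFrame,
    signatures: dict[str, pd.DataFrame],
    regulons: pd.DataFrame,
    new_survival: pd.DataFrame,
    config: PipelineConfig | None = None,
    covariates: list[str] | None = None,
) -> dict:
    """Project a fitted model into an independent cohort and assess survival.

    Cox models use the bundle's selected cell-type-group scores (or an
    explicit ``covariates`` list); risk groups split at
    ``config.risk_quantile`` and differences are tested by log-rank.
    """
    config = config or PipelineConfig.from_dict(bundle.config)
    with _stage("project"):
        projected = project_cohort(bundle, new_expr, signatures,
                                   filter_regulons(regulons, new_expr.index))
    group_scores = projected["group_scores"]
    with _stage("cluster_projected"):
        clustering = cluster_patients(group_scores,
                                      k=bundle.n_patient_clusters or "auto")
    covs = covariates or bundle.selected_features or list(group_scores.columns)
    covs = [c for c in covs if c in group_scores.columns]
    covs = _prune_collinear(group_scores[covs])
    with _stage("survival"):
        missing = sorted(set(group_scores.index) - set(new_survival.index))
        if missing:
            raise KeyError(f"survival table missing projected samples: {missing[:10]}")
        cox = fit_cox(group_scores[covs], new_survival)
        strat = stratify(cox.linear_predictors, config.risk_quantile, cox)
        km = {
            label: km_estimate(new_survival.loc[strat.labels[strat.labels == label].index])
            for label in ("high", "low") if (strat.labels == label).any()
        }
        if len(km) == 2:
            stat, p = logrank(strat.labels, new_survival)
        else:
            stat, p = float("nan"), float("nan")
            logger.warning("risk stratification produced a single group; log-rank skipped")
    report = {
        "projected": projected,
        "clustering": clustering,
        "cox": cox,
        "stratification": strat,
        "km": km,
        "logrank_statistic": stat,
        "logrank_p": p,
        "significant": bool(p < config.logrank_alpha) if p == p else False,
    }
    report["text"] = _text_report(report, covs, config)
    return report


def _prune_collinear(X: pd.DataFrame, max_abs_corr: float = 0.95) -> list[str]:
    """Drop covariates nearly collinear (|r| > max_abs_corr) with an earlier
    one; mirror-image cell type groups otherwise make the Cox information
    matrix singular."""
    kept: list[str] = []
    for col in X.columns:
        if any(abs(X[col].corr(X[k])) > max_abs_corr for k in kept):
            logger.info("dropping Cox covariate %s (collinear with an earlier one)", col)
            continue
        kept.append(col)
    return kept


def _text_report(report: dict, covs: list[str], config: PipelineConfig) -> str:
    cox = report["cox"]
    lines = [
        "Validation report",
        "=================",
        f"samples projected: {len(report['stratification'].labels)}",
        f"patient clusters: k={report['clustering'].k}",
        f"Cox covariates: {', '.join(covs)}",
        "coefficients:",
    ]
    for name, beta in cox.coefficients.items():
        lines.append(f"  {name}: beta={beta:+.4f} (se={cox.standard_errors[name]:.4f})")
    lines += [
        f"events: {cox.n_events}",
        f"risk split at quantile {config.risk_quantile:.2f} "
        f"(high = {int((report['stratification'].labels == 'high').sum())} samples)",
        f"log-rank chi2={report['logrank_statistic']:.4f} p={report['logrank_p']:.4g} "
        f"({'significant' if report['significant'] else 'not significant'} at "
        f"alpha={config.logrank_alpha})",
    ]
    return "\n".join(lines)


def save_fit_outputs(out_dir: str | Path, bundle: FittedModelBundle,
                     manifest: RunManifest, art: dict) -> None:
    """Write the primary fit outputs as TSV/JSON under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_bundle(bundle, out / "model_bundle.json")
    manifest.save(out / "manifest.json")
    art["feature_table"].to_csv(out / "feature_table.tsv", sep="\t")
    art["subgroup_scores"].to_csv(out / "subgroup_scores.tsv", sep="\t")
    art["tf_activity"].to_csv(out / "tf_activity.tsv", sep="\t")
    art["pathway_activity"].to_csv(out / "pathway_activity.tsv", sep="\t")
    art["eigengenes"].to_csv(out / "module_eigengenes.tsv", sep="\t")
    art["kme"].to_csv(out / "module_kme.tsv", sep="\t")
    art["group_scores"].to_csv(out / "cell_type_group_scores.tsv", sep="\t")
    art["patient_clusters"].labels.to_csv(out / "patient_clusters.tsv", sep="\t")
    pd.DataFrame({
        "confirmed_fraction": art["consensus"].confirmed_fraction,
        "selected": art["consensus"].selected,
    }).to_csv(out / "selected_features.tsv", sep="\t")
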
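# tmeflow

Integrated tumor-microenvironment (TME) profiling from bulk RNA-seq, for
computational oncologists who want to go from an expression matrix to
survival-relevant, cross-cohort-portable immune features.

Bulk deconvolution estimates *how much* of each cell type a tumor contains;
transcription-factor (TF) activity inference estimates *what those cells are
doing*. `tmeflow` joins the two: redundant deconvolution features are merged
into per-cell-type subgroups, TF activities are condensed into co-activity
modules (WTCNA), and subgroups whose scores share a correlation profile with
the module eigengenes are clustered into **cell type groups** — features such
as `Dendrogram_red_turquoise.group_2` that capture *cell types in a shared
regulatory state* (e.g. resting vs cytotoxic NK cells). A consensus
shadow-feature selector picks the groups that discriminate patient
landscapes, and Cox proportional-hazards models on the selected group scores
stratify patients into risk groups.

## The method in brief

1. **Deconvolution grid** — engines × signatures; NNLS solves
   min‖S·f − b‖², f ≥ 0 on linear-scale (2^x − 1) expression and normalizes
   f to the simplex; a marker-enrichment engine scores mean cohort-z
   expression of marker genes. External feature tables can be imported.
2. **Subgroups** — features are filtered (zero-heavy / low-variance) and
   same-cell-type pairs with max(Pearson r, ρ_p) ≥ 0.7 are merged greedily
   until a fixed point, where ρ_p = 2·cov(x,y)/(var x + var y) is the
   proportionality coefficient. Subgroup score = mean of z-scored members.
3. **Activities** — TF activity is the slope t-statistic of the sample's
   expression regressed on the signed regulon weight vector (ULM); pathway
   activity is the per-coefficient t-statistic of one joint regression on
   all footprint-weight columns (MLM).
4. **WTCNA** — unsigned adjacency a_ij = |cor|^β (β = 6), topological
   overlap, average-linkage clustering with a static cut; modules are named
   by colors, scored by their eigengene (PC1 of member activities), and
   annotated by hub TFs (kME > 0.8 and top-decile connectivity) whose
   unique, most-variable targets feed hypergeometric ORA.
5. **Integration** — subgroups with a significant (p < 0.05) module
   correlation are Ward-clustered (ward.D2 semantics) on their correlation
   profiles, one dendrogram per module group, into cell type groups with
   per-sample scores.
6. **Selection & survival** — Boruta-style shadow-feature selection repeated
   over 100 seeds keeps groups confirmed in strictly more than 90% of runs;
   Cox linear predictors split patients at the median (or top-34%) into
   high/low risk, compared by Kaplan–Meier curves and the log-rank test at
   α = 0.01.

A fully specified synthetic-cohort generator (Dirichlet cell fractions with
a dual-NK patient-landscape axis, planted TF modules, exponential survival
tied to a planted group score) makes every stage testable offline.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
import tmeflow as tme

cfg = tme.PipelineConfig(rng_seed=1, boruta_repeats=25)
cohort = tme.generate_cohort(n_samples=60, n_genes=1400, config=cfg)
bundle, manifest, art = tme.run_fit(
    cohort.expression, cohort.signatures, cohort.regulons,
    cohort.pathway_model, cohort.immune_sets, cfg)

print("TF modules:", {m: len(tfs) for m, tfs in art["modules"].items()})
print("patient clusters: k =", art["patient_clusters"].k)
print("selected features:", bundle.selected_features)
ari = adjusted_rand_score(cohort.truth.patient_landscape.values,
                          art["patient_clusters"].labels.values)
print(f"landscape recovery ARI = {ari:.3f}")

val = tme.generate_cohort(n_samples=60, n_genes=1400,
                          config=tme.PipelineConfig(rng_seed=2))
report = tme.run_validate(bundle, val.expression, val.signatures,
                          val.regulons, val.survival, cfg)
print(f"validation log-rank chi2 = {report['logrank_statistic']:.2f}, "
      f"p = {report['logrank_p']:.2e}")
```

prints

```
TF modules: {'turquoise': 15, 'blue': 15, 'brown': 15, 'yellow': 12, 'grey': 3}
patient clusters: k = 2
selected features: ['Dendrogram_turquoise_blue_brown.group_2',
 'Dendrogram_turquoise_blue_brown.group_4',
 'Dendrogram_yellow.group_1', 'Dendrogram_yellow.group_2']
landscape recovery ARI = 1.000
validation log-rank chi2 = 23.57, p = 1.20e-06
```

The four planted TF modules are recovered (three TFs land in the unassigned
"grey" bin), the patients split into the two simulated landscapes exactly
(ARI = 1.0), and the cell-type-group risk model carries to an independent
cohort, where the median split of the Cox linear predictor separates
survival at p ≈ 10⁻⁶.

The same flow is available from the shell:

```bash
tme simulate --n-samples 120 --n-genes 2000 --seed 1 --out-dir data/
tme run-all --mode fit --expression data/expression.tsv --signatures data/ \
    --regulons data/regulons.tsv --pathway-weights data/pathway_weights.tsv \
    --seed 1 --out-dir fit/
tme run-all --mode validate --expression data/expression.tsv --signatures data/ \
    --regulons data/regulons.tsv --survival data/survival.tsv \
    --bundle fit/model_bundle.json --out-dir val/
```

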
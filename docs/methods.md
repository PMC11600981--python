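# Methods

## Overview

`tmeflow` reconstructs a tumor-microenvironment feature-integration
workflow as a tested, reusable pipeline. Its unit of analysis is a bulk
RNA-seq cohort on the log2(TPM+1) scale; its final products are per-sample
**cell type group** scores — clusters of deconvolution feature subgroups
that share a correlation profile with TF co-activity module scores — and a
survival risk stratification built on them. Every stage is a pure function
of (inputs, config, seed): rerunning with the same configuration reproduces
outputs exactly, and all randomness derives from one root seed via named
child streams (CRC-mixed `SeedSequence`s), so a stage can be re-run in
isolation.

## Deconvolution engines

Two transparent engines stand in for the zoo of published deconvolution
methods, because everything downstream is agnostic to engine internals and
externally computed feature tables can be imported (`engine="external"`):

* **NNLS** solves min‖S·f − b‖², f ≥ 0 per sample on linear-scale
  (2^x − 1) expression — mixing is linear in TPM space — then normalizes f
  to sum 1. Rank-deficient signatures fall back to a clipped pseudo-inverse
  with a warning. All-zero solutions are reported as uniform fractions plus
  a flag rather than NaN, so downstream correlation code always sees finite
  values.
* **Marker enrichment** scores a sample as the mean cohort-z-scored
  expression of a cell type's marker genes (derived from a signature matrix
  by specificity ratio when no explicit sets are given). Sets with fewer
  than 3 usable (measured, non-constant) genes are dropped.

## Feature subgroups

Features are filtered when their fraction of exact zeros exceeds 0.75 or
their variance falls below 1e-8. Within each cell type, the pair of current
representatives with the highest association — the maximum of Pearson r and
the proportionality coefficient ρ_p = 2·cov(x,y)/(var x + var y), a
symmetric concordance measure that penalizes scale-discordant pairs — is
merged whenever it reaches 0.70, the subgroup representative is recomputed
as the mean of its z-scored member features, and the search repeats until no
pair reaches the threshold. Greedy best-pair merging avoids the chaining
artifacts of single-linkage components; lexicographic tie-breaking on the
smallest member id makes the partition invariant to input column order.
Merging operates on z-scored values because engine outputs live on
incommensurate scales (fractions vs enrichment t-like scores).

## Regulator activities

TF activity is inferred with a univariate linear model: for each TF and
sample, the sample's full expression vector is regressed (with intercept) on
the TF's signed regulon weight vector, zero for non-targets; the activity is
the slope **t-statistic**, which normalizes regulon size away. Pathway
activity uses the multivariate analogue: one joint regression per sample on
all footprint-weight columns, per-coefficient t-statistics as activities.
With a single pathway the MLM reduces exactly to the ULM. TFs with fewer
than 5 usable targets are skipped and logged. |t| is capped at 50; the cap
binds only when the residual variance collapses (noiseless constructions).

## TF co-activity modules (WTCNA)

The weighted-network workflow applied to TF activities: unsigned adjacency
a_ij = |cor(activity_i, activity_j)|^β with β = 6 (the conventional
unsigned default), topological-overlap similarity, average-linkage
clustering of 1 − TOM, and a **static cut at the 0.90 quantile of merge
heights**. On a TF-scale network nearly all merges are within-module and
only the last few join modules, so the cut belongs high in the merge-height
distribution; lower quantiles systematically fragment planted modules
(median ARI ≈ 0.73 at the 0.75 quantile vs ≥ 0.91 at 0.90 on the 4-module
benchmark). Clusters below 5 members fall into "grey"; modules whose
eigengenes correlate ≥ 0.8 are merged; surviving modules are color-named by
decreasing size. The static cut (rather than a dynamic hybrid cut) keeps
the procedure fully specified and deterministic.

Module scores are eigengenes — PC1 across samples of the standardized
member activities, sign-oriented so cor(eigengene, mean member activity) ≥ 0
and scaled to unit variance. kME(TF, M) = cor(activity_TF, eigengene_M) is
computed for all TFs against all modules. Hub TFs need kME > 0.8 **and**
weighted whole-network degree at or above the 0.90 quantile; the degree
percentile is global by default (`degree_scope="module"` is available), and
modules may legitimately have no hubs. Modules are grouped by PCA (first
two PCs) of the module × pathway correlation matrix followed by Ward
clustering with silhouette-chosen k ∈ {2..5}; group ids concatenate member
colors. ORA tests each module's hub targets — restricted to expressed genes
in the regulon network, uniquely claimed by one module, and in the top 20%
by expression variance — against user-supplied gene sets with the upper-tail
hypergeometric distribution, BH-corrected within module.

## Cell type groups

Subgroups with at least one module correlation at p < 0.05 are clustered —
one dendrogram per module group, on Euclidean distances between their
correlation-profile rows restricted to that group's modules — with Ward
linkage in the ward.D2 sense (scipy's `ward` on observations, which matches
R's `hclust(..., "ward.D2")` on Euclidean distances; verified against
Rscript in the test suite). Two cut modes exist: `absolute` (height 5, the
setting appropriate to large cohorts with tens of subgroups and wide
profiles) and the default `quantile` mode, which cuts at the lower third
(0.33) of merge heights. At desk scale — a handful of surviving subgroups
over 2–4 module columns — Ward root heights sit near 3, so an absolute cut
of 5 degenerates to a single all-subgroup cluster; the lower-third cut
yields groups of roughly two subgroups, the granularity the integrated
features are meant to have. Groups are numbered in dendrogram leaf order
and named `Dendrogram_<module-group colors>.group_<k>`; user-directed
post-hoc merges produce `group_combined_<k>` ids. Group scores are the mean
of z-scored member subgroup scores (single-member groups reduce to the
z-scored member); z-scoring is always within-cohort, so projected scores
have zero mean in the projection cohort by construction.

## Consensus shadow-feature selection

Each Boruta-style run appends a column-permuted shadow copy of every
feature, fits a random-forest classifier, and scores a feature a hit when
its impurity importance exceeds the best shadow importance (permutation
importance available by flag). Hit counts are tested against
Binomial(iterations, ½), two-sided, Bonferroni-corrected across currently
undecided features at α = 0.01; decisions are made as soon as the test
resolves and anything undecided at `max_iter = 50` stays Tentative. Every
feature keeps its shadow throughout: the shadow pool is the null
distribution, and thinning it (as some implementations do after rejection)
weakens the hit criterion and inflates false confirmations. The forest uses
50 trees — at the pipeline's feature counts (tens of features) importance
rankings are stable well below conventional forest sizes, and this is what
keeps the 100-seed consensus inside the pipeline's runtime envelope on a
single CPU; the power/false-selection benchmark below is insensitive to
larger forests. The consensus wrapper runs seeds seed+1..seed+100 and
selects features confirmed in **strictly more than 90%** of runs (91/100
selects, 90/100 does not); Tentative never counts as Confirmed.

## Survival analysis

Cox proportional-hazards models are fitted by lifelines (Efron tie
handling) with convergence tightened to ~1e-12 so the partial-likelihood
optimum is met to analytic precision; linear predictors are centered at
covariate means. The pipeline's validation flow drops covariates with
|pairwise r| > 0.95 before fitting (mirror-image groups from different
dendrograms are otherwise exactly collinear); direct `fit_cox` calls still
error on separation or constant covariates. Risk groups split at a
linear-predictor quantile — median by default, 0.66 for the top-34%
variant — with "high" meaning strictly above the threshold, so ties at the
boundary and degenerate all-equal predictors resolve to "low"
deterministically. Kaplan–Meier curves come from the product-limit
estimator and group differences from the Mantel–Haenszel log-rank test,
reported as significant at α = 0.01.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, at a
default scale of 120 samples × 2,000 genes × 8 cell types × 60 TFs in 4
modules (runs in under a second):

* **Fractions** are Dirichlet draws (base concentration 2). Half the
  samples form landscape 1 (concentration 8 for the resting-NK-like type,
  0.8 for the active-NK-like type), half landscape 2 with the axis
  reversed.
* **Expression** is the linear mixture signature @ fractions with
  element-wise lognormal noise (σ = 0.2 on the natural-log scale — a
  mid-range bulk measurement noise), log2(1+·)-transformed. Signatures give
  each cell type 40 markers boosted 20–40×.
* **TF activities**: module j's score is the z-scored fraction of its
  dedicated cell type; each member TF adds N(0, 0.5²) TF-level noise,
  giving within-module activity correlations near 0.8 (within the ≥ 0.6 /
  ≤ 0.2 within/between design band) and a TF-versus-module recovery ceiling
  of ~0.89. Each TF shifts its 15 unique signed targets on the log2 scale
  by 0.8 × weight × activity.
* **Pathways**: 14 footprint columns with PROGENy-style names; the first
  four carry the corresponding module's target weights, the rest are random
  footprints — so pathway annotation has a true signal and the MLM design
  stays full-rank.
* **Survival** is exponential with log-hazard = hazard_beta × planted dual-NK
  score (baseline median 1000 days), censored administratively at 5 years
  plus uniform dropout.

What the generator does **not** emulate: count-level noise (negative
binomial, library size), batch effects, correlated marker leakage between
cell types, and real signature misspecification. Passing tests therefore
demonstrate correctness of the pipeline's logic and its statistical
calibration under the stated model, not performance on real tumors.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` use: exact-recovery NNLS on 100
noiseless 5-type mixtures; activity recovery over 10 default cohorts;
module recovery over 20 seeds (ARI ≥ 0.9 in ≥ 18); the selection benchmark
with 5 informative features (standardized separation d = 2) among 45 noise
features at n = 100, 20 replicates; survival power at a planted hazard
ratio of 3 (hazard_beta = ln 3 / (2√(2/π)), the log-HR between median-split
halves of a standard-normal score) with n = 200 over 50 simulations, and
null calibration over 500 simulations; and one full fit/validate pair at
the default cohort scale.

## Known limitations

* The two stand-in deconvolution engines do not reproduce published
  methods' absolute scales; imported tables are the route for faithful
  engine outputs.
* ULM activities share variance between TFs with overlapping regulons; the
  generator plants disjoint targets, so cross-talk is untested.
* The absolute cut height of 5 for cell type groups is scale-dependent by
  construction; use it only with cohort sizes comparable to the original
  setting, otherwise keep the quantile mode.
* Hot/intermediate/cold immune classes are within-cohort tertiles of the
  mean immune score — a reporting convention, not a calibrated threshold.
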
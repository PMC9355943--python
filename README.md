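# coexmod

Cell-type-specific co-expression module analysis for fatty-liver disease
transcriptomics: robust WGCNA module discovery in single-cell RNA-seq data,
projection of module activity into bulk RNA-seq cohorts, covariate-adjusted
bootstrap association with histological phenotypes, module preservation
testing in an external single-cell reference, and hypergeometric mapping of
candidate gene lists and curated gene sets onto modules.

The package is aimed at computational biologists who want to ask, for each
major liver cell type: *which groups of genes are co-regulated, do those
programmes exist in healthy tissue, does their activity track lobular
inflammation or fibrosis once BMI, age and sex are controlled for, and do
they harbour GWAS candidate genes?*  Because patient-level single-cell data
of this kind are typically not shareable, the package ships a first-class
synthetic-data generator that emulates the full study design — droplet-style
negative-binomial counts from multiple cell types across donors with batch
effects, planted co-expression modules, a healthy reference in which only
some modules stay co-expressed, and a bulk cohort whose module activities
depend linearly on ordinal histology grades — so every stage is verifiable
against a known ground truth.

## The statistics at the core

**Network construction (rWGCNA).** Per cell type, gene–gene Pearson
correlations on per-donor z-scored expression are soft-thresholded,
`a_ij = max(r_ij, 0)^β` (signed-hybrid), with β chosen as the smallest power
whose connectivity distribution fits a scale-free law with signed R² ≥ 0.8.
Gene similarity is the topological overlap

```
TOM_ij = ( Σ_u a_iu a_uj + a_ij ) / ( min(k_i, k_j) + 1 − a_ij ),   k_i = Σ_u a_iu
```

Robustness comes from a consensus: the TOM is recomputed on 20 resamples of
80% of the cells and combined by the elementwise median before modules are
cut from the average-linkage tree of `1 − TOM`.  Each module is summarized by
its eigengene (first principal component) and by kIM, the intramodular
connectivity `kIM(g) = Σ_{m ∈ M, m≠g} TOM(g, m)`, which serves as the gene's
centrality weight.

**Module activity.** In any dataset, a module's activity per observation is
the kIM-weighted mean of z-scored module-gene expression — the statistic that
projects single-cell modules into an independent bulk cohort.

**Association.** Standardized activity is regressed on one ordinal phenotype
(lobular inflammation 0–2, fibrosis 0–1, steatosis 0–2) plus BMI, age and
sex; inference uses bootstrap percentile 95% CIs and two-sided percentile
p-values, Benjamini–Hochberg corrected across modules within each phenotype.

**Preservation.** A module is preserved in an external reference if its mean
within-module pairwise correlation exceeds that of size-matched random gene
sets (permutation p, BH-corrected).

**Enrichment.** Candidate lists and GMT gene sets are tested per module with
upper-tail hypergeometric probabilities computed in exact log-gamma
arithmetic against the universe of genes that entered module discovery.

## Worked example

Run the bundled reduced-size synthetic study end to end (≈10 s):

```bash
coexmod --config configs/pipeline-small.yaml --seed 11 --out-dir out \
    run-all --sim-config configs/sim-small.yaml
```

```
{
 "cell_types_analysed": ["T1"],
 "n_cells_post_qc": 1000,
 "n_clusters": 9,
 "n_modules": 5,
 "n_significant_associations": 1
}
```

Five modules are discovered in the simulated cell type.  The association
table (`out/results/association.tsv`) for lobular inflammation reads:

```
module_id      beta    ci_low  ci_high  p_boot    p_adj  significant
   M-T1-1 -0.176918 -0.349297 0.012933   0.068 0.170000        False
   M-T1-2  0.059328 -0.112989 0.234684   0.456 0.456000        False
   M-T1-3 -0.130316 -0.295182 0.021488   0.112 0.186667        False
   M-T1-4  0.079130 -0.096026 0.252325   0.372 0.456000        False
   M-T1-5  0.397643  0.246363 0.568934   0.004 0.020000         True
```

`beta` is the change in module activity, in SD units, per unit of lobular
inflammation after adjusting for BMI, age and sex.  Exactly one module is
flagged — the discovered module matching the planted one, whose generative
slope was 0.5 SD/unit; the 95% CI (0.25, 0.57) covers it.  The same module
captures 9 of the 20 simulated candidate genes
(`enrichment_candidates.tsv`, hypergeometric p = 6.4e-8), and the
preservation table shows adjusted p < 0.05 only for the two modules planted
as preserved in the healthy reference.

The stages are also available as separate subcommands (`simulate`,
`preprocess`, `modules`, `associate`, `enrich`) operating on MatrixMarket
triplets, TSV count/metadata tables, GMT collections and module JSON — or
directly as library functions (see `docs/methods.md`).

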
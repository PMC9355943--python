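# Methods

This note documents the models, defaults and design choices behind
`coexmod`, and what the synthetic-data generator does and does not emulate.

## Pipeline overview

Per cell type: QC → library-size log-normalisation → per-donor scaling →
consensus WGCNA (correlation → soft threshold → TOM → quantile tree cut →
eigengene merge → QC) → kIM weights.  Across datasets: kIM-weighted activity
projection, preservation permutation tests in a healthy single-cell
reference, OLS + bootstrap association against histology grades in bulk, and
hypergeometric enrichment of candidate genes and GMT collections.

## Preprocessing

* **Cell QC** keeps cells with detected-gene count in
  `[min_genes=200, max_genes=6000]` and mitochondrial fraction
  ≤ `max_mito_frac=0.2` (prefix `MT-`).  These are droplet-data conventions;
  they are config-exposed because the appropriate values are data-dependent.
* **Single-cell normalisation** is median-library-size scaling followed by
  `log1p`: `x → log1p(x · m / total)`, `m` the median cell total.
* **Bulk normalisation** is the DESeq median-of-ratios size factor.  Note a
  structural property: multiplying one sample by `c` rescales every gene's
  geometric mean by `c^(1/n)`, so the normalized matrix changes by exactly
  that global scalar.  All downstream statistics consume per-gene z-scores,
  which are invariant to it.
* **Batch correction** z-scores each gene within each donor, removing
  additive donor shifts and donor-level variance differences.  Donors with a
  single cell are rejected rather than silently passed through.
* **Clustering** is PCA (deterministic full SVD with fixed component signs)
  → kNN graph → Leiden with the RB-configuration objective; `resolution=1.0`,
  `k=15`, 30 PCs.  Cluster annotation is nearest-centroid against reference
  mean profiles by Spearman correlation (floor `min_corr=0.5`, minimum
  50 shared genes) — a deliberate simplification of anchor-based label
  transfer that is accurate when cell types are well separated.

## Network construction

* **Correlation**: Pearson on per-donor-scaled data (the scaling already
  tempers outliers; biweight midcorrelation is out of scope).
* **Network type**: signed-hybrid by default (negative correlations
  truncated to zero) so a module reads as a coherently regulated programme;
  unsigned is available by config.
* **Soft power**: smallest β in 1..20 whose binned degree distribution fits
  `log10 freq ~ log10 k` with signed R² ≥ 0.8, where the sign convention
  scores a *decreasing* power-law fit positively.  If no power reaches the
  target the best-fitting power is used with a logged warning.  The power is
  chosen once on the full cell-type data and reused across resamples so that
  consensus differences reflect sampling only.
* **Consensus**: 20 resamples of ⌈80%⌉ of cells without replacement;
  elementwise-median TOM.  The median was chosen over a lower quantile as a
  robust, parameter-free combiner.
* **Tree cut**: average linkage on `1 − TOM`, cut at the 0.99 quantile of
  merge heights; clusters below `min_module_size=10` become background.
  This static cut is a documented simplification of the dynamic hybrid
  algorithm.  Its operating regime matters: it relies on background genes
  carrying weak diffuse connectivity (as count data always do, via residual
  library/compositional correlation) so that planted modules join the tree
  well below the background agglomeration.  On idealized TOMs with an exactly
  independent background the cut degrades — a known limitation.
* **Merging**: iterative, highest eigengene correlation first, while above
  `merge_corr=0.85`; ties break by module id.  **Module QC** keeps modules
  with ≥ 10 genes and mean gene–eigengene correlation (kME) ≥ 0.3.
* **kIM** is intramodular connectivity computed from the consensus TOM
  (matching the centrality the figures call "kIM"), kept separate from kME,
  which is only used for QC.

## Activity, association, preservation

* **Activity** = Σ_g w_g z_g with w the normalized kIM restricted and
  renormalized over genes present in the target dataset; z-scores use the
  target dataset's own per-gene means and SDs, since modules are projected
  into cohorts with no shared scale.  Raw and unit-variance standardized
  activities are both returned; the standardized one enters regression so
  the phenotype coefficient is in SD-of-activity per phenotype unit.
* **Association**: OLS with intercept on one numerically encoded phenotype
  (inflammation 0–2, fibrosis 0–1, steatosis 0–2) plus BMI, age and
  sex (male indicator).  Inference is by bootstrap percentile with
  `B=1999` by default (999 in the heavy simulation checks): CI = 2.5/97.5
  percentiles; two-sided p = `2·min(#{β*≤0}+1, #{β*≥0}+1)/(B+1)`, capped at
  1 — the +1 correction keeps p strictly positive.  Bootstrap refits use a
  batched normal-equations solver verified against per-resample least
  squares; rank-deficient resamples are redrawn (error above 10%).  BH runs
  across modules within each phenotype.  Missing covariates trigger listwise
  deletion with the per-model n reported; fewer than 20 complete samples is
  an error.
* **Preservation**: observed statistic is the mean off-diagonal pairwise
  correlation among module genes in the reference; the null re-draws
  size-matched gene sets from reference-expressed genes `M_perm=999` times;
  empirical p = `(1+#{null ≥ obs})/(M_perm+1)`, BH across tested modules.  A
  z-score against the permutation null is reported for comparability with
  composite preservation statistics, which are out of scope.  Modules with
  fewer than 5 genes expressed in the reference are skipped with a logged
  reason rather than tested.

## Enrichment

Upper-tail hypergeometric p summed in log-gamma space (exact at p ≈ 1e-7 and
far below, where normal approximations fail).  The universe defaults to the
genes that entered module discovery for the tested cell types — the
conservative choice, config-overridable, with N always reported.  GMT sets
are filtered to sizes in `[5, 500]` after universe intersection.  The module
overlap matrix stores |genes_c ∩ genes_r| / |genes_c| with the diagonal fixed
at 0 and rows/columns ordered by average-linkage clustering of the
symmetrized matrix.

## Synthetic-data generator

The generator defines the study conditions the tests run under.

* **Single-cell counts**: for gene g in cell c,
  `log μ = base_g + de_{t(c),g} + load_g·f_{m,c} + shift_{d(c)} + ε`,
  with factor `f ~ N(0, factor_sd=2)` per cell and module, loadings
  `U(0.8, 1.2)`, cell-type identity offsets `N(0, 0.5)`, donor shifts
  `N(0, 0.3)` and per-donor dispersion multipliers `U(0.8, 1.25)`, gene-cell
  noise `N(0, 0.3)`.  Counts are gamma-Poisson with dispersion 0.3 and a
  log-normal library factor (mean total 1,500 over 600 genes).  Defaults:
  10 donors × 200 cells, 5 modules of 30 genes per cell type.
* **Module baseline offset**: factor-carrying genes sit at a gene-intrinsic
  baseline `−1.5` logs below background.  This keeps each module a small
  share of the cell library, as real modules are of real transcriptomes.
  Without it, at this scaled-down gene count the planted bursts dominate
  cell totals and library normalisation induces strong compositional
  correlations that distort both module detection and the preservation null.
* **Reference**: new donors (5) and cells; preserved modules keep their
  factors; destroyed modules have the factor re-attached to random
  background genes (which then also get the baseline offset), so the
  original members decay to background co-expression.
* **Bulk cohort**: n = 184 with 24 grade-0 controls; cases draw inflammation
  uniformly from {0,1,2} and fibrosis from {0,1}; BMI ~ N(42, 6),
  age ~ N(48, 11), 70% female.  Module activity =
  `Σ_p slope_p·pheno_p + 0.1·z(BMI) + 0.1·z(age) + 0.2·male + ε`, with
  `var(ε)` set so the marginal activity variance is 1 — slopes are therefore
  expressed in SD-of-activity per phenotype unit, the scale the association
  stage estimates.  Gene response is `1.0·load_g` logs per activity SD with
  bulk dispersion 0.05, which keeps measurement attenuation of the slope
  negligible.  The default effect grid plants 0.5 SD/unit of inflammation on
  one module and nothing elsewhere.
* **Candidate genes**: planted members drawn from target modules; the
  remainder uniformly from the whole gene pool, so an unplanted list
  overlaps modules at the hypergeometric rate.

**What passing tests do and do not show.**  The generator reproduces
overdispersion, sparsity, donor batch structure, cell-type identity and
factor-driven co-expression, but not zonation, doublets, ambient RNA,
cell-cycle structure, realistic cell-type abundances, or gene-length/GC
effects in bulk.  Recovery results therefore demonstrate the pipeline's
correctness under its stated model, not performance guarantees on arbitrary
real data.

## Numerical choices and degenerate inputs

Zero-variance genes get zero correlations (logged); eigengene sign is
oriented along the module's mean expression with deterministic behaviour
under data sign flips; cluster and module ids are re-ranked by size with
lexicographic tie-breaks so outputs are stable; every stochastic stage takes
an explicit integer seed and `run-all` output is byte-identical across runs
with the same configs.  Problem sizes in the test-suite simulations (e.g.
2,000 cells × 600 genes for recovery, 20 bulk replicates for coverage,
3,000 genes for the 20-module preservation scenario) were chosen to estimate
each property stably while keeping the default suite quick to run.

## Known limitations

Static quantile tree cut (see above); a diffuse "background" module can
appear when residual compositional correlation passes the kME floor —
harmless to planted-module recovery but worth inspecting in outputs;
nearest-centroid annotation assumes reference and target share expression
scale after log-normalisation; no mixed-effects or ordinal-link models; no
cell-type deconvolution of bulk samples; gene identifiers are opaque strings
with no symbol/Ensembl mapping layer.
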
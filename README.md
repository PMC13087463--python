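# pcqtl

Multi-gene *cis*-QTL mapping on principal components of neighboring-gene
expression clusters.

Standard eQTL mapping regresses one gene on one variant at a time and misses
variants whose effects are spread across several neighboring, co-expressed
genes. This package implements the complete multi-gene workflow:

1. **Cluster calling** — per chromosome, Spearman correlations between all
   gene pairs of residualized expression at a Bonferroni threshold of
   `0.05 / C(N, 2)`; an iterative sliding-window scan (window size 50 down
   to 2, left to right) records a window as a cluster when at least 70% of
   its pairs are significantly correlated (`0.7 * C(n, 2) <= m`) and none of
   its genes is already clustered.
2. **PC phenotypes** — per-cluster PCA on the gene-gene correlation matrix;
   every PC becomes a mappable phenotype. The normalized shared variance of
   PC1, `(sum_i l_i^2 - 1) / (n - 1) * 100`, is 100% for perfectly correlated
   clusters and 0% for uncorrelated genes.
3. **Fine-mapping** — a from-scratch sum-of-single-effects model (L = 10,
   per-effect prior variances estimated by empirical Bayes, residual variance
   re-estimated each iteration, monotone ELBO) on individual-level dosages in
   a ±1 Mb window at MAF ≥ 0.05, yielding 95% credible sets filtered at
   purity ≥ 0.5, plus a genotype-shuffle calibration null.
4. **QTL statistics** — nominal per-variant scans, permutation-based
   phenotype-level empirical p-values with a Beta-tail approximation
   (FastQTL scheme), Storey q-values (three FDR conditions: eQTL, pcQTL,
   joint), and allelic fold-change estimation from linear-scale expression.
5. **Effects** — PIP-weighted log2 aFC of each credible set on every cluster
   gene, max |aFC| and CV summaries, and strand-aware lead-variant-to-TSS
   distances.
6. **Colocalization & grouping** — five-hypothesis Bayes-factor
   colocalization (SuSiE lbf rows for QTLs, Wakefield ABFs for GWAS);
   credible-set groups are connected components of the PP_H4 ≥ 0.75 graph;
   pcQTLs in groups without any eQTL are novel; GWAS hits are linked per
   variant-trait pair.
7. **Enrichment** — nine structural/functional cluster labels (promoter
   sharing, overlap, shared enhancer, paralogs, GO, CTCF/TAD crossing) with
   covariate-adjusted logistic enrichment against sampled null clusters, and
   PIP-weighted variant annotations.
8. **Simulator** — LD-structured synthetic cohorts with known causal
   variants, cluster structure, aFC ground truth and GWAS traits, emitted as
   plain-text BED/VCF/TSV/JSON.

## CLI

```bash
pcqtl simulate --preset distributed_weak --seed 1 --out cohort/
pcqtl run-all --cohort cohort/ --out results/ --seed 1
```

Stages are also available individually (`preprocess`, `call-clusters`,
`make-pcs`, `finemap`, `scan`, `coloc`, `group`, `effects`, `enrich`); each
reads the cohort directory, re-derives its cheap upstream dependencies
deterministically, writes its TSV outputs and a manifest with the config
hash. Thresholds live in a YAML config (`--config`), defaulting to the
published constants (MAF 0.05, ±1 Mb, L = 10, purity 0.5, coverage 0.95,
PP_H4 0.75, q < 0.05).

Cohort directories contain `expression.bed`, `genotypes.vcf`,
`covariates.tsv`, `genes.tsv` and optionally `gwas.tsv`,
`expression_linear.bed` (positive-scale expression for aFC), and annotation
tables (`enhancer_links.tsv`, `paralogs.tsv`, `go_terms.tsv`,
`ctcf_peaks.tsv`, `tad_boundaries.tsv`).

## Layout

```
src/pcqtl/
  io_formats.py        phenotype BED / VCF / gene-table / GWAS / covariate IO
  preprocess.py        covariate residualization, expression filter
  cluster_calling.py   correlation matrices, sliding-window clusters, nulls
  pc_phenotypes.py     cluster PCA, normalized shared variance
  finemap.py           sum-of-single-effects fine-mapping, credible sets
  qtl_stats.py         nominal scans, permutation FDR, q-values, aFC
  effects_annotation.py  PIP-weighted effects, TSS distances
  coloc_grouping.py    colocalization, credible-set groups, GWAS linking
  enrichment.py        cluster labels, logistic enrichment, PIP annotations
  simulate.py          synthetic cohorts with ground truth
  config.py, pipeline.py, cli.py
```
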
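# metamir

Multi-study transcriptome meta-analysis with miRNA targetome integration.

The package implements an integrated differential-expression workflow over
several case/control expression studies:

1. **Study quality control** (`metamir.study_qc`) — six concordance indices
   (IQC, EQC, AQCg, AQCp, CQCg, CQCp), each `-log10` of a permutation or
   hypergeometric p-value, plus PCA visualization coordinates and an explicit
   rank-based exclusion rule.
2. **Meta differential expression** (`metamir.meta_de`) — per-study penalized
   two-sample t (`t = d / (se + s0)` with a SAM-style fudge constant),
   cross-study combination by Fisher's method and the maxP statistic,
   Benjamini–Hochberg FDR control, cross-study sign-consistency filtering,
   overlap-gene lists, and heatmap gene selection. Within-study quantile
   normalization is available as a preprocessing step.
3. **miRNA differential expression** (`metamir.mirna_de`) — sd-ratio
   (σ/σ_max) variance filtering, pooled-variance t-tests on log2 values, and
   joint p / q / fold-change thresholds with top-k selection.
4. **Targetome integration** (`metamir.targetome`) — per-miRNA three-source
   intersection of predicted targets restricted to 3′-UTR sites, union over
   the selected miRNAs, and overlap with the meta-DE gene list.
5. **Gene-set enrichment** (`metamir.enrichment`) — hypergeometric
   over-representation analysis against a GMT collection.
6. **Network analysis** (`metamir.network`) — mixed gene–gene / miRNA–gene
   graph assembly, degree-based hub extraction, connectivity loss on hub
   removal, GraphML/SIF export.

Everything is exercised on synthetic multi-study data with planted ground
truth (`metamir.synthetic`), including an optional corrupted study for QC
detection, so the full pipeline is testable without any downloads.

## Command-line usage

Generate a synthetic fixture bundle and run the whole pipeline:

```sh
metamir simulate --outdir bundle --seed 1 --corrupt-study 2
metamir run-all --config run.yaml --seed 1 --outdir results
```

`run.yaml` lists the input paths and per-stage options:

```yaml
expression:
  - {matrix: bundle/expression_study1.tsv, study_id: study1}
  - {matrix: bundle/expression_study2.tsv, study_id: study2}
  - {matrix: bundle/expression_study3.tsv, study_id: study3}
annotation: bundle/annotation.tsv
mirna_matrix: bundle/mirna_expression.tsv
mirna_annotation: bundle/mirna_annotation.tsv
genesets: bundle/genesets.gmt
ppi: bundle/ppi.tsv
targets:
  alpha: bundle/targets_alpha.tsv
  beta: bundle/targets_beta.tsv
  gamma: bundle/targets_gamma.tsv
outdir: results
meta: {combine: both, meta_alpha: 0.05, heatmap_fdr: 1.0e-4}
qc: {n_qc_genes: 500, n_perm: 500}
mirna: {p_threshold: 0.001, q_threshold: 0.01, fc_threshold: 2.0, top_k: 5}
```

Each stage is also available as a subcommand (`qc`, `meta-de`, `mirna-de`,
`targets`, `enrich`, `network`) operating on intermediate files. Exit codes:
0 success, 2 validation error, 3 stage failure. Runs are byte-reproducible
under a fixed seed.

## Data formats

All inputs are tab-delimited UTF-8 text: expression matrices (first column
`gene_id`, then sample ids; log2 scale), sample annotations (`sample_id`,
`group`, `study_id`), GMT gene sets, scored interaction edges (`gene_a`,
`gene_b`, `combined_score` in [0,1]) and target predictions (`mirna_id`,
`gene_id`, `region`, optional `score`). Networks are exported as GraphML
and SIF.
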
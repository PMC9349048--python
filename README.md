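# cellatlas

Post-clustering analysis toolkit for multi-phenotype single-nucleus
brain atlases. Given clustered UMI count matrices (plus, optionally,
alignment records, all-vs-all protein scores and GO maps), it covers:

* **Read filtering** — discard multi-mapped alignments, spliced reads
  spanning gaps > 50 kb, and splice junctions whose terminal
  dinucleotides are not GT/AG, GC/AG or AT/AC on either genomic
  orientation (`cellatlas.preprocess`).
* **Nucleus QC and normalization** — keep nuclei with 200–2,000
  detected genes and ≤ 1% mitochondrial UMIs; CP10K normalization;
  pseudo-bulk vs bulk Pearson correlations.
* **Cluster expression, markers, DEGs** — per-cluster mean within-cell
  UMI fractions (× 1e6), one-vs-rest Wilcoxon rank-sum markers
  (min.pct 0.25, ln-fold-change 0.25, positive only), rank-sum DEGs
  gated at FDR < 0.05, fold > 1.25, > 20% expressing; correlation-
  distance Ward dendrograms with gene-bootstrap branch support
  (`cellatlas.expression`, `cellatlas.hier`).
* **Orthology and GO transfer** — reciprocal best hits from BLAST
  tabular bit scores (ties disqualify), priority-ordered GO transfer
  with a best-hit fallback (`cellatlas.orthology`).
* **Cross-species cluster correspondence** — pseudo-cells of 10 cells
  (summed UMIs → CP10K → per-gene z-scores over marker orthologues),
  neighbor-voting mean-AUROC cluster similarity, 1 − AUROC Ward
  dendrograms, and correspondence networks (edges at AUROC > 0.80,
  second hits within 0.05 of the top) (`cellatlas.crossmap`).
* **Compositional differential abundance** — Dirichlet-multinomial
  likelihood-ratio test with a reference-cluster constraint and
  automatic reference selection, gated at FDR < 0.2 and > 1.3-fold
  change; pooled Fisher's exact route (FDR < 0.001) and cross-species
  direction-consistent convergence calls (`cellatlas.composition`).
* **GO enrichment** — one-sided Fisher tests against a background of
  genes with mean CP10K > 1 across the clusters of interest, excluding
  the query DEGs; significant at FDR < 0.05 with ≥ 2 genes
  (`cellatlas.enrichment`).
* **Synthetic data** — a two-species atlas simulator with planted
  markers, orthologue maps, replicate-jittered compositions with
  planted phenotype effects, and a spliced-SAM generator with known
  pass/fail reads, so every stage is testable without external data
  (`cellatlas.synthetic`).

## Command line

All functionality is exposed through the `atlas` entry point:

```bash
atlas simulate --out sim --seed 1                 # synthetic atlas + truth
atlas run -c config.yaml                          # staged pipeline + manifest
atlas preprocess filter-sam --sam reads.sam --genome genome.fa --out pass.tsv
atlas preprocess qc --matrix sim/sp1 --mito-genes mito.txt --out qc_sp1 --report qc.tsv
atlas expr summarize|markers|degs|dendro ...
atlas ortho rbh|transfer-go ...
atlas crossmap pseudocells|auroc|network|dendro ...
atlas compo test --mode dm|fisher --fdr 0.2 --min-fold 1.3 --reference auto ...
atlas enrich go ...
```

`atlas run` executes the stages (simulate → qc → markers → crossmap →
network → composition) in dependency order, records every threshold,
seed and output digest in `manifest.json`, and reuses cached artifacts
when a stage's parameters and inputs are unchanged. A minimal
`config.yaml`:

```yaml
out_dir: run1
seed: 7
simulate:
  n_clusters: 8
  n_genes: 600
composition:
  groups: [gyne, queen]
```

## File formats

Counts are Matrix Market (`matrix.mtx` genes × cells) with `genes.tsv`
and `cells.tsv` sidecars; alignments are SAM with FASTA genomes; score
tables are BLAST tabular (outfmt 6 or a 3-column subset); all results
are TSV, dendrograms Newick, networks edge-list TSV or GraphML.
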
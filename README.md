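# chromaquant

Spike-in calibrated chromatin quantitation and histone-turnover analysis at
desk scale. The package reimplements, as tested and reusable Python, a
yeast chromatin analysis pipeline:

- **synthetic data** (`chromaquant.simulate`) — toy genome annotation,
  condition-specific mononucleosome fragments with planted occupancy
  changes, two-species spike-in ChIP/input mixtures with a known global
  scaling, dual-tag (Flag/V5) barcoded reads with planted duplicates, and
  stranded negative-binomial count matrices with planted DE genes. Every
  generator is deterministic for a fixed seed and records its ground truth.
- **coverage tracks** (`chromaquant.coverage`) — MAPQ filtering, fixed-length
  read extension and pile-up, RPM normalization, mutant−WT difference maps,
  replicate Pearson checks, and strand-oriented TSS-relative window matrices
  (20 bp windows over ±800 bp, windows overlapping neighbouring genes
  masked).
- **spike-in calibration** (`chromaquant.calibration`) — the
  `(input_ref × chip_target)/(input_target × chip_ref)` calibration factor
  from non-orthologous read tallies, calibrated coverage, fold-enrichment
  tracks with zero→1 substitution, and bidirectional Poisson q-value tracks.
- **nexus preprocessing** (`chromaquant.nexus`) — 6 bp random + 4 bp fixed
  barcode stripping and barcode-aware duplicate removal (best alignment per
  identical barcode at identical 5′ coordinates).
- **turnover statistics** (`chromaquant.turnover`) — depth-normalized
  per-window tag counts, new/old ratios, a window-paired repeated-measures
  contrast for WT-vs-mutant group differences, and Benjamini–Hochberg
  q-values.
- **clustering & set intersections** (`chromaquant.cluster`) — deterministic
  six-cluster k-means of Δoccupancy matrices, upper-tail hypergeometric
  intersection p-values, rate-class enrichment tables, and n-way Venn set
  algebra.
- **stranded expression** (`chromaquant.expression`) — sense/antisense
  counting under a configurable dUTP-style orientation, a documented NB
  Wald differential-expression test, the FDR < 5% & |log2FC| ≥ 0.585
  threshold rule, and 2^−ΔΔCT qPCR fold changes.

All file formats are plain text: BED (0-based half-open) with optional
`species=`/`barcode=` columns for alignments, bedGraph for tracks, FASTQ
for reads, TSV for matrices and reports.

## CLI

```sh
chromaquant simulate-genome --n-genes 50 --seed 1 --out-prefix toy
chromaquant coverage --alignments frags.bed --chrom-sizes toy.chrom.sizes \
    --extension 148 --out cov.bedgraph
chromaquant calibrate --chip chip.bed --input input.bed \
    --chrom-sizes toy.chrom.sizes --out calibrated.bedgraph
chromaquant nexus-prep --fastq raw.fastq --out trimmed.fastq
chromaquant nexus-dedup --alignments aln.bed --out dedup.bed
chromaquant de --wt wt.tsv --mut mut.tsv --fdr 0.05 --lfc 0.585 --out de.tsv
```

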
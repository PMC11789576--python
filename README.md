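# snpipe

A desk-scale toolkit for the computational side of pre-indexed droplet
single-nucleus RNA-seq of FFPE tumor samples — the assay family that
labels nuclei with sample pre-indexes during reverse transcription, pools
them into droplets, and captures total RNA with random primers so that
degraded, crosslinked FFPE material (including tiny needle biopsies) still
yields single-nucleus transcriptomes rich in non-coding RNA.

It is written for computational biologists who want every stage of such a
pipeline as tested, composable library code, with synthetic-data
generators that plant known structure so each stage can be validated
without any external download.

## What it implements

**Reads → counts.** Read 1 carries a 30 nt cell barcode (sample pre-index
‖ droplet barcode) plus an 8 nt UMI; read 2 is a 300–800 bp cDNA fragment
with primer and poly(dA) artifacts. The pipeline trims artifacts, corrects
barcodes onto acceptor whitelists when uniquely within Hamming distance 2
(ambiguous hits are discarded), assigns inserts to genes by exact k-mer
voting against the synthetic transcriptome, and collapses
(barcode, gene, UMI) triples into molecule counts.

**Cell calling & barnyard QC.** Nuclei-containing barcodes are called at
the steepest descent (knee) of the smoothed log10(genes) vs log10(rank)
curve. For two-species mixing experiments, per-barcode species purity
p = max(nA, nB)/(nA + nB) classifies doublets (p < 0.90), giving the
collision-rate estimate such assays report. QC filters drop nuclei with
< 200 genes, then genes in < 3 nuclei.

**Expression statistics.** log1p library-size normalization, variance-
ranked variable genes, cluster mean profiles, binned-control module
scores, one-vs-rest Wilcoxon markers (min.pct = 0.25, logFC ≥ 0.25, BH
adjusted), and RNA-biotype detection tables.

**Cluster-specific lncRNA–mRNA pairs.** Over the top-2000 variable genes:
cluster profiles are split by biotype; lncRNA×mRNA pairs with Pearson
r > 0.85 across cluster profiles enter a pair×cluster activity matrix
(min of the two min-max-scaled profiles); pairs whose cosine against the
best one-hot cluster indicator falls below 0.95 are eliminated; the rest
are assigned to their argmax cluster and tabulated per cell type.

**CNV score & subclones.** A windowed estimator (moving average of
reference-centred, clipped expression along the genome) produces a
cells × regions matrix; the per-cell CNV score is the quadratic sum
Σᵣ valueᵣ²; malignant cells are split off by deterministic 1-D 2-means
(or a 3-SD rule) and clustered into subclones by Ward linkage, with mean
profiles, gain/loss calls and composition tables.

**Recurrent heterogeneous programs (RHPs).** Per-sample NMF sweeps
(ranks 4–9, deterministic NNDSVD init) yield programs summarized by their
top-50 genes; programs recurring across ranks (≥ 35/50 overlap) are kept,
and robust programs from all samples are clustered by shared-gene
fraction — clusters spanning ≥ 2 samples are RHPs with top-50 consensus
signatures, scored per cell via module scores.

**Synthetic data.** Generators for the two-species transcriptome,
error-bearing FASTQ pairs with full ground truth, barnyard count matrices,
clustered counts with planted pairs/modules, multi-sample program data,
and CNV gain/loss profiles. All are deterministic given (config, seed);
see `docs/methods.md` for the generative models and their limits.

## Worked example

```python
import snpipe

cfg = snpipe.SimConfig(seed=0, n_cells_A=50, n_cells_B=50, reads_per_cell=200,
                       collision_rate=0.05, droplet_whitelist_size=500)
genes, seqs = snpipe.simulate_transcriptome(cfg)
truth = snpipe.simulate_reads(cfg, genes, seqs, "scratch/demo")
matrix, stats = snpipe.demux("scratch/demo/R1.fastq.gz", "scratch/demo/R2.fastq.gz",
                             cfg.layout, truth.preindex_whitelist,
                             truth.droplet_whitelist, genes, seqs)
print("read accounting:", stats)

matrix.var = snpipe.annotation_frame(genes).reindex(matrix.genes)
mix = snpipe.species_mix(matrix, purity_min=0.90)
print(f"barcodes: {mix.n_called}, doublets: {mix.n_doublets}, "
      f"doublet rate: {100 * mix.doublet_rate:.2f}%")
print(snpipe.biotype_counts(matrix, matrix.var).to_string())
```

prints

```
read accounting: {'reads_in': 24013, 'assigned': 24013}
barcodes: 94, doublets: 6, doublet rate: 6.38%
protein_coding    194
lncRNA             98
snoRNA             10
snRNA              10
miRNA              10
other              10
```

Every one of the ~24k error-free reads is assigned (nothing is too short,
ambiguous or unmapped on clean input). The 100 simulated nuclei occupy 94
barcodes because a planted 5% of barcodes host one nucleus of each
species; those six cross-species barcodes have purity ≈ 0.5 and are called
doublets, giving the 6.38% observed collision rate (6/94; small-n noise
around the planted 5%). The biotype table counts genes detected in at
least one barcode — all 300 simulated genes per species are seen at this
depth, half of them non-coding.

The same stages are available as a CLI for shell use:
`snpipe simulate`, `snpipe demux`, `snpipe qc`, `snpipe lncpairs`,
`snpipe cnv`, `snpipe programs` (see `snpipe --help`).

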
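# Methods

`snpipe` re-creates, at desk scale, the computational path of a pre-indexed
droplet single-nucleus RNA-seq assay for FFPE tumor samples: read
demultiplexing, cell calling and barnyard QC, and four downstream analyses
(marker/module statistics, cluster-specific lncRNA–mRNA pairs, windowed CNV
scoring with subclones, and cross-sample NMF meta-programs). This note
records the models, the defaults that matter, and the choices made where
the design was genuinely open.

## Read model and demultiplexing

Read 1 carries a 30 nt cell-specific barcode followed by an 8 nt UMI. The
30 nt barcode is the concatenation of a sample pre-index (ligated during
reverse transcription, before pooling) and a droplet barcode. Only the
30 nt total is fixed by the assay; the split is a library-design parameter
and defaults to 8 + 22. Read 2 is a cDNA fragment (300–800 bp) carrying
the RT primer at its 5' end and a poly(dA) tail from the dA-tailing step.

Processing steps:

- **Trimming** removes a leading primer match (≤ 1 substitution, no
  indels) and a trailing run of ≥ 3 A's. The dA run threshold of 3 equals
  the simulator's minimum tail length; a genuine A-rich 3' end can be
  clipped, which only shortens the evidence available to the assigner.
- **Barcode correction** merges an observed barcode onto a whitelist
  acceptor when it is *uniquely* within Hamming distance 2; two or more
  acceptors in range make the read ambiguous and it is discarded, never
  rescued by abundance priors. The default corrects the pre-index and
  droplet segments independently at the shared distance budget (each
  segment must resolve uniquely); a single-segment 30 nt mode is provided
  because the published description does not say which the original
  pipeline used. Correction is exact: it is tested against a brute-force
  all-pairs Hamming oracle, including ambiguous/unmatched statuses.
- **Gene assignment** is a deliberately small stand-in for a splice-aware
  aligner, valid only for the synthetic transcriptome: transcripts are
  rejection-sampled so that no 31-mer occurs in two genes, so exact 31-mer
  votes identify the source gene unambiguously on error-free reads. Votes
  are sampled at a configurable stride; a tie across genes is discarded as
  multimapped.
- **UMI counting** collapses identical (acceptor barcode, gene, UMI)
  triples; UMIs are scoped per cell. No UMI error correction is applied
  (a substituted UMI creates one spurious molecule; at a 1% per-base error
  rate this costs ≈ 8% inflation and leaves per-cell rank correlations
  with truth above 0.99).

Read accounting is conservative by construction: reads in = assigned +
too-short + unmatched + ambiguous + unmapped + multimapped, and the
pipeline logs every category.

## Cell calling and barnyard statistics

Barcodes are ranked by detected genes; the calling threshold sits at the
steepest descent of the smoothed log10(genes) vs log10(rank) curve. The
curve is resampled onto an evenly spaced log-rank grid (512 points) before
smoothing (Savitzky–Golay, linear, window 21) because raw ranks crowd the
tail and would dominate a finite-difference derivative through vanishing
x-spacing. The threshold is read off the smoothed curve at the knee, which
places it between the plateaus rather than snapping to either raw value;
barcodes strictly above it are called. A curve whose maximum absolute
smoothed slope is below 1.0 (in log-log units) has no knee and is an
error. The raw curve is always written out so any alternative rule can be
audited.

Species purity of a called barcode is the larger species fraction of its
UMIs; a barcode is a cross-species doublet when purity < 0.90 (the assay
reports no cutoff; 0.90 is configurable). The reported doublet rate is the
observed cross-species rate; the ×2 extrapolation to include same-species
collisions is available behind a flag but off by default, matching how the
assay's own rate was reported.

QC filtering applies, in order: drop nuclei with fewer than 200 detected
genes, then drop genes detected in fewer than 3 remaining nuclei. The
order matters and re-application is the identity. Mitochondrial genes are
recognized by symbol prefix (`MT-`/`mt-`, configurable), as the source
pipeline's rule is not stated.

## Expression substrate

Normalization is `log(1 + 1e4 · count / cell_total)` — a deliberate
simplification of variance-stabilizing normalization. It affects absolute
values but not the rank-based quantities used downstream; the residual
compositional effects it leaves are discussed under the generator below.
Variable genes are ranked by plain variance of normalized expression (ties
broken lexicographically for determinism). Markers use a one-vs-rest
Wilcoxon rank-sum test with Seurat-style pre-filters (min.pct 0.25, log
fold-change 0.25, positive only), exact enumeration for ≤ 20 cells and the
tie-corrected normal approximation otherwise, and Benjamini–Hochberg
adjustment within each cluster. Clustering itself is consumed as given
labels; graph clustering is not re-implemented.

Module scores follow the binned-control scheme: genes are placed into 25
equal-occupancy bins by mean expression; each signature gene draws 100
controls from its bin; the score is mean(signature) − mean(controls) per
cell. A consequence worth stating: when a shift δ is planted in a *large*
fraction of cells, the signature genes' bin assignment moves with them, so
the absolute score of shifted cells underestimates δ; the
shifted-minus-unshifted score contrast estimates δ regardless of the
shifted fraction, and that contrast is what the acceptance checks measure
(with homogeneous baselines the absolute score also lands near δ).

## lncRNA–mRNA pairs

The six steps: (1) average the top-2000 variable genes over clusters;
(2) split the profile by biotype into mRNA and lncRNA matrices; (3) keep
lncRNA×mRNA pairs with Pearson correlation across cluster profiles
strictly above 0.85; (4) build a pair × cluster activity matrix; (5) score
cluster specificity by cosine similarity against one-hot cluster
indicators; (6) eliminate pairs whose best cosine is below 0.95 and assign
the rest to their argmax cluster.

Two constructions were open:

- **Step 4.** The pair × cluster rule is min-of-minmax: each partner's
  profile is rescaled to [0, 1] and the pair's activity per cluster is the
  smaller value. A pair is active only where both partners are jointly
  elevated, and the rule reduces to a one-hot row in the clean case. A
  product rule is available behind a flag.
- **Step 5.** The cosine reference vectors are the one-hot cluster
  indicators, making the best cosine `max(activity)/‖activity‖` and the
  assignment the argmax entry. Closed forms used in tests: uniform
  activity over k clusters scores 1/√k; (1, 0.1, 0, 0) scores 1/√1.01.

Correlation over cluster profiles (not single cells) is the implemented
reading, since the step-2 matrices are cluster-level. Thresholds are
strict (> 0.85) and inclusive (≥ 0.95) respectively, matching "exceeds"
and "below … are eliminated".

**Evaluation semantics.** Planted pairs sharing a cluster have identical
one-hot signatures, so their cross-combinations are definitionally
indistinguishable from the planted pairs — any method satisfying the six
steps retains them. Precision is therefore scored against the generative
truth of the claim the method makes: a retained pair is correct iff both
genes are truly co-elevated in exactly the assigned cluster. Recall is
strict recovery of the planted list.

## CNV score and subclones

The windowed estimator is a simplified stand-in for a dedicated CNV
caller, and is labeled as such: genes are ordered along the genome; each
cell's per-gene residual against the diploid reference mean is clipped to
±3 reference SDs (with a floor at the median SD to guard near-silent
genes) and averaged in a centred 101-gene window per chromosome.
Chromosomes shorter than the window shrink it with a warning; window 1
returns the clipped residuals. Externally produced cells × regions
matrices can be imported from TSV, and the downstream stages are agnostic
to region provenance.

The per-cell CNV score is the quadratic sum over regions, Σ value² —
checked against a brute-force oracle and invariant to region permutation
and sign flips. Malignant/diploid calling offers two rules, both artifact
decisions because the source states none: deterministic 1-D 2-means
(centers initialized at the score min/max; the higher-mean group is
malignant) and a 3-SD rule (score > reference mean + 3 SD). Subclones come
from Ward-linkage hierarchical clustering of the malignant CNV rows cut at
k, with per-subclone mean profiles, ±t gain/loss calls (default t = 0.05),
cluster composition, and per-timepoint proportions when a covariate is
given. The subclone tree is the clustering dendrogram only; no
evolutionary model is implied.

## NMF programs and RHPs

Per sample, malignant-cell expression is centred per gene and clipped at
zero (keeping above-average signal), then factorized at ranks 4–9 with
NNDSVD initialization, so the sweep is deterministic given the data. Each
factor contributes a candidate program: its 50 top-loading genes. A
program is *robust* iff a factor at a different rank of the same sample
shares ≥ 35 of its top-50 genes; robust programs are deduplicated by
greedy neighbourhood selection (keep the program with the highest mean
overlap to its direct partners, drop those partners, repeat), which —
unlike collapsing whole connected components — survives chains of mixed
low-rank factors. Robust programs across samples are clustered by
average linkage on 1 − (shared top-gene fraction), cut at 0.8 (programs
sharing ≥ 10/50 genes can merge); clusters spanning ≥ 2 samples are RHPs.
An RHP's signature is its top-50 genes ranked by member count with a floor
of presence in half the contributing samples, mirroring the convention of
a fixed top-50 signature per program. The rank range, overlap threshold,
and cut height are artifact defaults in the spirit of the meta-program
literature; all are configurable and logged.

## Synthetic data: what it emulates, and what it does not

All generators are deterministic given (config, seed). Defaults are the
study conditions: 30 nt barcode (8 + 22), 8 nt UMI, 300–800 bp fragments,
geometric dA tails (mean 10, min 3), a residual cross-species collision
rate of 0.62% (the assay's reported barnyard doublet rate), substitution
errors only, and negative-binomial counts (gamma–Poisson, var = μ +
μ²/θ) — the standard single-cell count model, since the assay itself has
no generative model.

Count matrices emulate the *variable stratum plus housekeeping bulk* of a
real transcriptome:

- Background variable genes each follow one of ~10 shared multi-cluster
  programs (active in 3 to n_clusters − 2 clusters, fold 2, per-gene
  weight U(0.5, 1.5)) plus small per-gene wiggle. This reflects why genes
  are highly variable in real data — modular co-variation — and has a
  useful geometric consequence: a multi-cluster program correlates at most
  ≈ 0.5 with any one-hot profile and fails the pair-specificity cosine,
  so background genes cannot masquerade as cluster-specific pairs.
- Planted pairs (one lncRNA + one coding gene, 8-fold in exactly one
  cluster) are the only one-cluster spikes.
- A housekeeping ballast (4000 genes, lognormal mean 8, θ = 50, no
  cluster structure) carries most of each cell's library, as in real data
  where variable genes are a minority of counts. Without it, planted
  spikes shift cluster totals enough that per-cell scaling leaves a
  common-mode cluster offset which one-hot profiles pick up — a
  compositional artifact, not a biological signal. Ballast genes are
  excluded by variance ranking, as intended.
- CNV profiles use arm-scale events (100 contiguous genes of a 1200-gene,
  6-chromosome genome; gain ×1.5, loss ×0.5), one trunk gain shared by all
  malignant cells plus gain/loss pairs private to each of 3 subclones.
- Multi-sample program data use 400 malignant cells per sample, 3–8
  programs of 50 genes with graded gamma activities in one third of the
  cells; one program is shared across samples at ≥ 80% gene identity, and
  private programs are rejection-sampled below 10/50 mutual overlap.

What the generators do **not** emulate — and hence what passing tests do
not show about real data: ambient RNA soup structure, indel errors and
quality-score variation, UMI errors, within-species doublets, intron/exon
structure and splicing, batch effects, or the mean–variance relation of
any particular chemistry. Conclusions supported are of the form "the
implementation recovers what was planted under the stated model", not
performance claims about any real dataset.

## Problem sizes

Default verification sizes were chosen so the whole suite runs on a single
CPU in a few minutes: demultiplexing uses 200 nuclei × ~200k reads (exact
truth equality without errors; per-cell Spearman ≥ 0.95 at 1% errors);
cell calling 500 nuclei among 20,000 ambient barcodes; barnyard 2,000
barcodes; pairs 50 planted among 2,000 variable genes in 8 clusters of
100 cells; CNV 100 reference + 120 malignant cells over 1,200 genes; RHPs
4 samples × 10 seeds. `scripts/acceptance.py` re-runs all of these from
scratch for a given seed.

## Known limitations

- The k-mer assigner requires the k-mer-disjoint synthetic transcriptome;
  it is not an aligner and silently degrades on any other input.
- log1p library-size normalization leaves compositional effects that a
  variance-stabilizing normalization would reduce; downstream defaults are
  rank-based in part for this reason.
- The knee rule assumes a single cliff; multimodal rank curves (e.g.
  strongly heterogeneous nuclei content) may need the emitted raw curve
  and a manual threshold.
- Exact UMI deduplication slightly inflates molecule counts under
  sequencing errors.
- 2-means malignant calling assumes a bimodal score distribution; gradual
  aneuploidy spectra are better served by the 3-SD rule with an explicit
  diploid reference.
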
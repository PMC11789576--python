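"""Synthetic-data generators for every input the pipeline consumes.

The generators emulate a pre-indexed droplet single-nucleus library built
from two mixed species (a barnyard design): read 1 carries a 30 nt
cell-specific barcode (sample pre-index followed by the droplet barcode)
and an 8 nt UMI; read 2 is a transcript fragment flanked by the RT primer
and a poly(dA) tail. Count-level generators use a negative-binomial
expression model with planted cluster structure, correlated lncRNA-mRNA
pairs, shared NMF programs across samples, and copy-number gain/loss
segments, each accompanied by a ground-truth table so downstream stages can
be scored against what was planted.

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import BarcodeLayout
from .io import CountMatrix, FastqWriter, GeneAnnotation, annotation_frame

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for every generator, with one global seed.

    Read-level defaults mirror the published library: 30 nt barcode split
    8 + 22, 8 nt UMI, 300-800 bp cDNA fragments, a residual cross-species
    collision rate of 0.62% (the barnyard doublet rate the assay reports).
    """

    # --- transcriptome ---------------------------------------------------
    n_genes: Mapping[str, int] = field(
        default_factory=lambda: {
            "protein_coding": 100,
            "lncRNA": 50,
            "snoRNA": 5,
            "snRNA": 5,
            "miRNA": 5,
            "other": 5,
        }
    )
    n_mito_per_species: int = 2
    transcript_len_range: tuple[int, int] = (1000, 1600)
    kmer_len: int = 31  # seed length of the read-to-gene assigner

    # --- reads -----------------------------------------------------------
    n_cells_A: int = 100
    n_cells_B: int = 100
    reads_per_cell: int = 500
    collision_rate: float = 0.0062
    ambient_rate: float = 0.0
    substitution_error_rate: float = 0.0
    pcr_duplicate_rate: float = 0.2
    n_preindex: int = 16
    droplet_whitelist_size: int = 2000
    fragment_len_range: tuple[int, int] = (300, 800)
    dA_mean: float = 10.0
    dA_min: int = 3
    layout: BarcodeLayout = field(default_factory=BarcodeLayout)

    # --- count matrices --------------------------------------------------
    n_clusters: int = 8
    cells_per_cluster: int = 100
    base_mean: float = 3.0  # genes emulate the highly-variable stratum
    nb_theta: float = 2.0  # NB dispersion: var = mu + mu^2/theta
    n_patterns: int = 10
    pattern_fold: float = 2.0
    pattern_min_clusters: int = 3
    wiggle_sd: float = 0.05
    n_planted_pairs: int = 50
    pair_fold: float = 8.0
    module_size: int = 50
    module_delta: float = 1.0
    # stable housekeeping bulk: carries most of the library like the real
    # non-variable transcriptome, so planted spikes barely move cell totals
    n_ballast_genes: int = 4000
    ballast_mean: float = 8.0
    ballast_theta: float = 50.0

    # --- multi-sample programs -------------------------------------------
    n_samples: int = 4
    programs_per_sample: tuple[int, int] = (3, 8)
    program_size: int = 50
    program_gene_universe: int = 600
    program_strength: float = 3.0
    cells_per_sample: int = 400
    shared_overlap_min: float = 0.8
    max_private_overlap: int = 9  # of program_size, enforced by rejection

    # --- CNV -------------------------------------------------------------
    n_reference_cells: int = 100
    n_malignant_cells: int = 120
    n_subclones: int = 3
    cnv_gain_fold: float = 1.5
    cnv_loss_fold: float = 0.5
    segment_genes: int = 100  # arm-scale events span hundreds of genes

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("collision_rate", "ambient_rate", "substitution_error_rate", "pcr_duplicate_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.fragment_len_range[1] > self.transcript_len_range[0]:
            raise ValueError("fragment range must fit within every transcript")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# sequence helpers


def random_seqs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """n independent uniform DNA sequences of the given length."""
    arr = _BASES[rng.integers(0, 4, size=(n, length))]
    return ["".join(row) for row in arr]


def sample_whitelist(
    rng: np.random.Generator, n: int, length: int, min_dist: int = 0, max_tries: int = 200
) -> list[str]:
    """Distinct random barcodes, optionally at pairwise Hamming >= min_dist.

    Rejection-sampled; used for the pre-index set where the sequences must
    stay correctable at the configured Hamming budget.
    """
    chosen: list[np.ndarray] = []
    out: list[str] = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries * n:
            raise RuntimeError(f"could not place {n} barcodes at min distance {min_dist}")
        cand = rng.integers(0, 4, size=length)
        if min_dist > 1 and chosen:
            dists = np.array([(cand != c).sum() for c in chosen])
            if dists.min() < min_dist:
                continue
        seq = "".join(_BASES[cand])
        if seq in out:
            continue
        chosen.append(cand)
        out.append(seq)
    return out


def mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    """Apply per-base substitution errors at the given rate."""
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    s = list(seq)
    for i in pos:
        s[i] = "ACGT"[("ACGT".index(s[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(s)


# ---------------------------------------------------------------------------
# transcriptome


def simulate_annotation(
    n_genes: Mapping[str, int],
    species: Sequence[str] = ("A", "B"),
    n_mito_per_species: int = 0,
    gene_len_range: tuple[int, int] = (1000, 1600),
    genes_per_chrom: int = 60,
    rng: np.random.Generator | None = None,
) -> list[GeneAnnotation]:
    """Gene-level annotation on synthetic chromosomes, one disjoint gene set
    per species, laid out consecutively with fixed intergenic gaps."""
    rng = rng or np.random.default_rng(0)
    genes: list[GeneAnnotation] = []
    for sp_label in species:
        pos, chrom_i, on_chrom = 0, 1, 0
        gene_i = 0
        mito_left = n_mito_per_species
        for biotype, count in n_genes.items():
            for _ in range(count):
                length = int(rng.integers(gene_len_range[0], gene_len_range[1] + 1))
                gene_id = f"{sp_label}G{gene_i:05d}"
                if biotype == "protein_coding" and mito_left > 0:
                    prefix = "MT-" if sp_label == "A" else "mt-"
                    symbol = f"{prefix}{gene_id}"
                    mito_left -= 1
                else:
                    symbol = f"{sp_label}SYM{gene_i:05d}"
                genes.append(
                    GeneAnnotation(
                        gene_id=gene_id,
                        symbol=symbol,
                        biotype=biotype,
                        species=sp_label,
                        chrom=f"{sp_label}_chr{chrom_i}",
                        start=pos,
                        end=pos + length,
                        mito=symbol.startswith(("MT-", "mt-")),
                    )
                )
                pos += length + 500
                gene_i += 1
                on_chrom += 1
                if on_chrom >= genes_per_chrom:
                    chrom_i += 1
                    pos, on_chrom = 0, 0
    return genes


def simulate_transcriptome(
    cfg: SimConfig, with_sequences: bool = True
) -> tuple[list[GeneAnnotation], dict[str, str]]:
    """Two-species annotation plus transcript sequences sharing no k-mer.

    Sequences are rejection-sampled so that no ``cfg.kmer_len``-mer occurs
    in more than one gene, which makes the k-mer voting assigner exact on
    error-free reads.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = simulate_annotation(
        cfg.n_genes,
        n_mito_per_species=cfg.n_mito_per_species,
        gene_len_range=cfg.transcript_len_range,
        rng=rng,
    )
    if not with_sequences:
        return genes, {}
    k = cfg.kmer_len
    seen: set[str] = set()
    seqs: dict[str, str] = {}
    for g in genes:
        length = g.end - g.start
        for attempt in range(50):
            seq = random_seqs(rng, 1, length)[0]
            kmers = {seq[i : i + k] for i in range(length - k + 1)}
            if not kmers & seen:
                seen |= kmers
                seqs[g.gene_id] = seq
                break
        else:
            raise RuntimeError(f"could not place a k-mer-unique sequence for {g.gene_id}")
    return genes, seqs


# ---------------------------------------------------------------------------
# reads


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline has to recover."""

    nuclei: pd.DataFrame  # nucleus_id, species, preindex, droplet, barcode, doublet
    reads: pd.DataFrame  # read_id, nucleus_id, barcode, gene_id, umi, ambient
    preindex_whitelist: list[str]
    droplet_whitelist: list[str]

    def umi_count_matrix(self, gene_order: Sequence[str]) -> CountMatrix:
        """Distinct (barcode, gene, UMI) triples of non-ambient reads,
        tabulated as a barcode x gene matrix in sorted-barcode order."""
        real = self.reads[~self.reads["ambient"]]
        triples = real[["barcode", "gene_id", "umi"]].drop_duplicates()
        counts = triples.groupby(["barcode", "gene_id"]).size()
        barcodes = sorted(triples["barcode"].unique())
        b_idx = {b: i for i, b in enumerate(barcodes)}
        g_idx = {g: i for i, g in enumerate(gene_order)}
        rows = [b_idx[b] for b, _ in counts.index]
        cols = [g_idx[g] for _, g in counts.index]
        mat = sp.csr_matrix(
            (counts.to_numpy(), (rows, cols)), shape=(len(barcodes), len(gene_order))
        )
        return CountMatrix(mat, barcodes, list(gene_order))


def simulate_reads(
    cfg: SimConfig,
    genes: list[GeneAnnotation],
    seqs: dict[str, str],
    outdir: str | Path,
) -> GroundTruth:
    """Emit an R1/R2 FASTQ pair plus truth tables under ``outdir``.

    A fraction ``collision_rate`` of barcodes host one nucleus of each
    species (sharing the full 30 nt barcode — the residual doublets a
    barnyard experiment measures); ambient reads keep a valid barcode but
    draw their gene from the pooled background of both species.
    """
    if cfg.reads_per_cell <= 0:
        raise ValueError("reads_per_cell must be positive")
    rng = np.random.default_rng(cfg.seed)
    layout = cfg.layout
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    preindexes = sample_whitelist(
        rng, cfg.n_preindex, layout.preindex_len, min_dist=2 * layout.max_hamming + 1
    )
    droplets = sample_whitelist(rng, cfg.droplet_whitelist_size, layout.droplet_len)

    # per-species gene abundance profiles (shared across nuclei of a species)
    by_species = {s: [g.gene_id for g in genes if g.species == s] for s in ("A", "B")}
    probs = {s: rng.dirichlet(np.ones(len(ids))) for s, ids in by_species.items()}
    pooled_ids = by_species["A"] + by_species["B"]
    pooled_p = np.concatenate([probs["A"], probs["B"]]) / 2.0

    # assign nuclei to barcodes; a collision consumes one nucleus per species
    pool = {"A": list(range(cfg.n_cells_A)), "B": list(range(cfg.n_cells_B))}
    nuclei_rows = []
    used_droplets = iter(rng.permutation(droplets))
    nucleus_id = 0
    while pool["A"] or pool["B"]:
        preindex = preindexes[int(rng.integers(len(preindexes)))]
        droplet = next(used_droplets)
        barcode = preindex + droplet
        if pool["A"] and pool["B"] and rng.random() < cfg.collision_rate:
            members = [("A", pool["A"].pop()), ("B", pool["B"].pop())]
            doublet = True
        else:
            sp_choice = rng.choice([s for s in ("A", "B") if pool[s]])
            members = [(sp_choice, pool[sp_choice].pop())]
            doublet = False
        for species, _ in members:
            nuclei_rows.append(
                dict(
                    nucleus_id=f"N{nucleus_id:05d}",
                    species=species,
                    preindex=preindex,
                    droplet=droplet,
                    barcode=barcode,
                    doublet=doublet,
                )
            )
            nucleus_id += 1
    nuclei = pd.DataFrame(nuclei_rows)

    frag_lo, frag_hi = cfg.fragment_len_range
    read_rows = []
    read_i = 0
    with FastqWriter(outdir / "R1.fastq.gz") as r1, FastqWriter(outdir / "R2.fastq.gz") as r2:
        for nucleus in nuclei.itertuples():
            ids = by_species[nucleus.species]
            gene_choice = rng.choice(len(ids), size=cfg.reads_per_cell, p=probs[nucleus.species])
            ambient_mask = rng.random(cfg.reads_per_cell) < cfg.ambient_rate
            n_ambient = int(ambient_mask.sum())
            ambient_genes = (
                rng.choice(len(pooled_ids), size=n_ambient, p=pooled_p) if n_ambient else []
            )
            umis = random_seqs(rng, cfg.reads_per_cell, layout.umi_len)
            amb_iter = iter(ambient_genes)
            for j in range(cfg.reads_per_cell):
                ambient = bool(ambient_mask[j])
                gene_id = pooled_ids[next(amb_iter)] if ambient else ids[gene_choice[j]]
                tx = seqs[gene_id]
                flen = int(rng.integers(frag_lo, min(frag_hi, len(tx)) + 1))
                start = int(rng.integers(0, len(tx) - flen + 1))
                da = cfg.dA_min + int(rng.geometric(1.0 / max(cfg.dA_mean - cfg.dA_min, 1e-9))) - 1
                insert = layout.primer + tx[start : start + flen] + "A" * da
                n_copies = 1 + (1 if rng.random() < cfg.pcr_duplicate_rate else 0)
                for _ in range(n_copies):
                    r1_seq = mutate(nucleus.barcode + umis[j], rng, cfg.substitution_error_rate)
                    r2_seq = mutate(insert, rng, cfg.substitution_error_rate)
                    name = f"read{read_i:07d}"
                    r1.write(name, r1_seq)
                    r2.write(name, r2_seq)
                    read_rows.append(
                        dict(
                            read_id=name,
                            nucleus_id=nucleus.nucleus_id,
                            barcode=nucleus.barcode,
                            gene_id=gene_id,
                            umi=umis[j],
                            ambient=ambient,
                        )
                    )
                    read_i += 1
    reads = pd.DataFrame(read_rows)

    nuclei.to_csv(outdir / "truth_nuclei.tsv", sep="\t", index=False)
    reads.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
    pd.Series(preindexes).to_csv(outdir / "preindex_whitelist.tsv", sep="\t", index=False, header=False)
    pd.Series(droplets).to_csv(outdir / "droplet_whitelist.tsv", sep="\t", index=False, header=False)
    return GroundTruth(nuclei, reads, preindexes, droplets)


# ---------------------------------------------------------------------------
# count-level generators


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson mixture; var = mu + mu^2/theta."""
    lam = rng.gamma(shape=theta, scale=np.maximum(mean, 1e-12) / theta)
    return rng.poisson(lam)


@dataclass
class CountsTruth:
    labels: pd.Series  # cluster label per cell (index = barcode)
    planted_pairs: pd.DataFrame  # lnc_id, mrna_id, cluster
    module_genes: list[str]
    module_cells: list[str]
    log_mean: np.ndarray  # cells x genes expected log-mean multipliers


def simulate_count_matrix(
    cfg: SimConfig, genes: list[GeneAnnotation] | None = None
) -> tuple[CountMatrix, CountsTruth]:
    """Clustered NB counts with planted lncRNA-mRNA pairs and a module set.

    Background genes covary through a small number of smooth latent
    programs, each elevating at least ``pattern_min_clusters`` clusters, so
    background co-expression is never cluster-specific; each planted pair
    (one lncRNA, one protein-coding gene) is co-elevated ``pair_fold``-fold
    in exactly one cluster. The module gene set is shifted by
    ``module_delta`` (log units) in a designated half of the cells.
    """
    rng = np.random.default_rng(cfg.seed)
    if genes is None:
        genes = simulate_annotation(cfg.n_genes, species=("A",), rng=rng)
    gene_ids = [g.gene_id for g in genes]
    biotypes = np.array([g.biotype for g in genes])
    n_genes = len(gene_ids)
    n_cells = cfg.n_clusters * cfg.cells_per_cluster
    labels = np.repeat(np.arange(cfg.n_clusters), cfg.cells_per_cluster)

    lnc_idx = np.flatnonzero(biotypes == "lncRNA")
    mrna_idx = np.flatnonzero(biotypes == "protein_coding")
    if cfg.n_planted_pairs > min(len(lnc_idx), len(mrna_idx)):
        raise ValueError("not enough lncRNA/protein_coding genes for the requested pairs")
    pair_lnc = rng.choice(lnc_idx, size=cfg.n_planted_pairs, replace=False)
    pair_mrna = rng.choice(mrna_idx, size=cfg.n_planted_pairs, replace=False)
    pair_cluster = np.arange(cfg.n_planted_pairs) % cfg.n_clusters

    # log-mean multiplier per (gene, cluster): every background gene varies
    # through one of a few shared multi-cluster programs (that is what makes
    # a gene highly variable in the first place), never through a private
    # one-cluster spike — those are reserved for the planted pairs
    log_mult = rng.normal(0.0, cfg.wiggle_sd, size=(n_genes, cfg.n_clusters))
    pattern_members = set(pair_lnc) | set(pair_mrna)
    patterns = np.zeros((cfg.n_patterns, cfg.n_clusters))
    max_active = max(cfg.n_clusters - 2, cfg.pattern_min_clusters)
    for p in range(cfg.n_patterns):
        k_active = int(rng.integers(cfg.pattern_min_clusters, max_active + 1))
        active = rng.choice(cfg.n_clusters, size=k_active, replace=False)
        patterns[p, active] = np.log(cfg.pattern_fold)
    for gi in range(n_genes):
        if gi in pattern_members:
            continue
        w = rng.uniform(0.5, 1.5)
        log_mult[gi] += w * patterns[int(rng.integers(cfg.n_patterns))]
    for lnc, mrna, cl in zip(pair_lnc, pair_mrna, pair_cluster):
        log_mult[lnc, cl] += np.log(cfg.pair_fold)
        log_mult[mrna, cl] += np.log(cfg.pair_fold)

    base = rng.lognormal(mean=np.log(cfg.base_mean), sigma=0.6, size=n_genes)
    cell_log_mean = log_mult[:, labels].T + np.log(base)[None, :]

    module_pool = [
        i for i in range(n_genes) if i not in pattern_members and biotypes[i] == "protein_coding"
    ]
    module_genes_idx = rng.choice(module_pool, size=min(cfg.module_size, len(module_pool)), replace=False)
    module_cells_idx = rng.choice(n_cells, size=n_cells // 2, replace=False)
    cell_log_mean[np.ix_(module_cells_idx, module_genes_idx)] += cfg.module_delta

    counts = _nb_sample(rng, np.exp(cell_log_mean), cfg.nb_theta)

    if cfg.n_ballast_genes > 0:
        ballast_base = rng.lognormal(np.log(cfg.ballast_mean), 0.4, size=cfg.n_ballast_genes)
        ballast = _nb_sample(
            rng, np.tile(ballast_base, (n_cells, 1)), cfg.ballast_theta
        )
        ballast_genes = simulate_annotation(
            {"protein_coding": cfg.n_ballast_genes},
            species=("A",),
            genes_per_chrom=500,
            rng=rng,
        )
        ballast_genes = [
            dataclasses.replace(g, gene_id=f"HK{i:05d}", symbol=f"HK{i:05d}", chrom=f"hk_{g.chrom}")
            for i, g in enumerate(ballast_genes)
        ]
        counts = np.hstack([counts, ballast])
        genes = list(genes) + ballast_genes
        gene_ids = gene_ids + [g.gene_id for g in ballast_genes]
        cell_log_mean = np.hstack(
            [cell_log_mean, np.tile(np.log(ballast_base), (n_cells, 1))]
        )

    barcodes = [f"CELL{i:05d}" for i in range(n_cells)]
    cm = CountMatrix(sp.csr_matrix(counts), barcodes, gene_ids, annotation_frame(genes))
    truth = CountsTruth(
        labels=pd.Series(labels, index=barcodes, name="cluster"),
        planted_pairs=pd.DataFrame(
            {
                "lnc_id": [gene_ids[i] for i in pair_lnc],
                "mrna_id": [gene_ids[i] for i in pair_mrna],
                "cluster": pair_cluster,
            }
        ),
        module_genes=[gene_ids[i] for i in module_genes_idx],
        module_cells=[barcodes[i] for i in module_cells_idx],
        log_mean=cell_log_mean,
    )
    return cm, truth


def simulate_barnyard_counts(
    cfg: SimConfig,
    n_barcodes: int = 2000,
    umis_per_barcode: float = 1000.0,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Species-labeled counts for called barcodes, with planted collisions.

    Each barcode is a cross-species doublet with probability
    ``collision_rate``; singlets draw an ``ambient_rate`` fraction of their
    UMIs from the pooled two-species background.
    """
    rng = np.random.default_rng(cfg.seed)
    n_a = max(cfg.n_genes.get("protein_coding", 50), 10)
    gene_ids = [f"AG{i:04d}" for i in range(n_a)] + [f"BG{i:04d}" for i in range(n_a)]
    species = np.array(["A"] * n_a + ["B"] * n_a)
    p_a = np.concatenate([rng.dirichlet(np.ones(n_a)), np.zeros(n_a)])
    p_b = np.concatenate([np.zeros(n_a), rng.dirichlet(np.ones(n_a))])
    pooled = (p_a + p_b) / 2.0

    doublet = rng.random(n_barcodes) < cfg.collision_rate
    own_species = rng.choice(["A", "B"], size=n_barcodes)
    counts = np.zeros((n_barcodes, 2 * n_a), dtype=np.int64)
    for i in range(n_barcodes):
        total = max(int(rng.poisson(umis_per_barcode)), 1)
        if doublet[i]:
            n_first = rng.binomial(total, 0.5)
            counts[i] = rng.multinomial(n_first, p_a) + rng.multinomial(total - n_first, p_b)
        else:
            own = p_a if own_species[i] == "A" else p_b
            n_amb = rng.binomial(total, cfg.ambient_rate)
            counts[i] = rng.multinomial(total - n_amb, own)
            if n_amb:
                counts[i] += rng.multinomial(n_amb, pooled)
    barcodes = [f"BC{i:05d}" for i in range(n_barcodes)]
    var = pd.DataFrame({"species": species}, index=gene_ids)
    truth = pd.DataFrame(
        {"barcode": barcodes, "doublet": doublet, "species": own_species}
    ).set_index("barcode")
    return CountMatrix(sp.csr_matrix(counts), barcodes, gene_ids, var), truth


def simulate_barcode_rank(
    n_cells: int = 500,
    n_ambient: int = 20000,
    cell_mean: float = 2000.0,
    ambient_mean: float = 30.0,
    seed: int = 0,
) -> tuple[dict[str, int], set[str]]:
    """Genes-detected-per-barcode map for a rank-curve with a planted cliff:
    nuclei-containing barcodes around ``cell_mean`` detected genes, ambient
    barcodes around ``ambient_mean``. Returns (map, set of true nuclei)."""
    rng = np.random.default_rng(seed)
    cells = np.maximum(_nb_sample(rng, np.full(n_cells, cell_mean), theta=20.0), 1)
    ambient = np.maximum(_nb_sample(rng, np.full(n_ambient, ambient_mean), theta=2.0), 1)
    out: dict[str, int] = {}
    truth: set[str] = set()
    for i, v in enumerate(cells):
        name = f"CELLBC{i:05d}"
        out[name] = int(v)
        truth.add(name)
    for i, v in enumerate(ambient):
        out[f"AMB{i:05d}"] = int(v)
    return out, truth


# ---------------------------------------------------------------------------
# multi-sample NMF programs


def simulate_multisample_programs(
    cfg: SimConfig,
) -> tuple[list[tuple[str, CountMatrix]], dict]:
    """Per-sample malignant count matrices with planted expression programs.

    Each sample carries 3-8 programs of ``program_size`` genes with graded
    per-cell activities; one designated program is shared across all
    samples with >= ``shared_overlap_min`` gene overlap, while private
    programs are rejection-sampled to overlap < ``max_private_overlap``
    genes with every other planted program.
    """
    if cfg.n_samples < 2:
        raise ValueError("need at least two samples")
    if cfg.program_size > cfg.program_gene_universe:
        raise ValueError("program size exceeds gene universe")
    rng = np.random.default_rng(cfg.seed)
    universe = [f"PG{i:05d}" for i in range(cfg.program_gene_universe)]
    shared_core = rng.choice(cfg.program_gene_universe, size=cfg.program_size, replace=False)
    shared_core_set = set(shared_core)

    all_program_sets: list[set[int]] = [shared_core_set]

    def _draw_private() -> set[int]:
        for _ in range(500):
            cand = set(rng.choice(cfg.program_gene_universe, size=cfg.program_size, replace=False))
            if all(len(cand & other) < cfg.max_private_overlap for other in all_program_sets):
                return cand
        raise RuntimeError("could not place a sufficiently disjoint private program")

    samples: list[tuple[str, CountMatrix]] = []
    truth: dict = {"programs": {}, "shared_gene_set": [universe[i] for i in sorted(shared_core)]}
    lo, hi = cfg.programs_per_sample
    for s in range(cfg.n_samples):
        sample_id = f"S{s}"
        n_prog = int(rng.integers(lo, hi + 1))
        # per-sample shared variant: swap out up to 20% of the core genes
        n_swap = int(rng.integers(0, int(cfg.program_size * (1 - cfg.shared_overlap_min)) + 1))
        keep = rng.choice(sorted(shared_core_set), size=cfg.program_size - n_swap, replace=False)
        outside = [i for i in range(cfg.program_gene_universe) if i not in shared_core_set]
        swapped = rng.choice(outside, size=n_swap, replace=False)
        prog_sets = [set(keep) | set(swapped)]
        for _ in range(n_prog - 1):
            newset = _draw_private()
            all_program_sets.append(newset)
            prog_sets.append(newset)

        n_cells = cfg.cells_per_sample
        base = rng.lognormal(np.log(cfg.base_mean), 0.5, size=cfg.program_gene_universe)
        log_mean = np.tile(np.log(base), (n_cells, 1))
        activities = np.zeros((n_cells, n_prog))
        for p, pset in enumerate(prog_sets):
            active_cells = rng.choice(n_cells, size=max(n_cells // 3, 10), replace=False)
            act = rng.gamma(2.0, 0.5, size=len(active_cells))
            activities[active_cells, p] = act
            gidx = np.array(sorted(pset))
            log_mean[np.ix_(active_cells, gidx)] += np.log1p(
                cfg.program_strength * act
            )[:, None]
        counts = _nb_sample(rng, np.exp(log_mean), cfg.nb_theta)
        barcodes = [f"{sample_id}_C{i:04d}" for i in range(n_cells)]
        samples.append((sample_id, CountMatrix(sp.csr_matrix(counts), barcodes, list(universe))))
        truth["programs"][sample_id] = [
            sorted(universe[i] for i in pset) for pset in prog_sets
        ]
    return samples, truth


# ---------------------------------------------------------------------------
# CNV profiles


def simulate_cnv_profiles(
    cfg: SimConfig, genes: list[GeneAnnotation] | None = None
) -> tuple[CountMatrix, dict]:
    """NB counts for diploid reference cells plus malignant subclones.

    Each subclone carries its own gain (x``cnv_gain_fold``) and loss
    (x``cnv_loss_fold``) segments of ``segment_genes`` contiguous genes,
    applied to the expression means before sampling; all malignant cells
    additionally share one trunk gain segment. Overlapping segments with
    conflicting folds raise an error.
    """
    rng = np.random.default_rng(cfg.seed)
    if genes is None:
        genes = simulate_annotation(
            {"protein_coding": 1200}, species=("A",), genes_per_chrom=200, rng=rng
        )
    order = sorted(range(len(genes)), key=lambda i: (genes[i].chrom, genes[i].start))
    genes = [genes[i] for i in order]
    gene_ids = [g.gene_id for g in genes]
    n_genes = len(genes)
    seg_len = cfg.segment_genes
    n_segments_needed = 1 + 2 * cfg.n_subclones
    if n_segments_needed * seg_len > n_genes:
        raise ValueError("annotation too small for the requested subclone segments")

    # non-overlapping contiguous gene blocks, trunk first
    starts = np.arange(n_segments_needed) * (n_genes // n_segments_needed)
    segs = []
    segs.append(dict(lo=int(starts[0]), hi=int(starts[0]) + seg_len, fold=cfg.cnv_gain_fold, subclone=-1))
    for c in range(cfg.n_subclones):
        g_lo = int(starts[1 + 2 * c])
        l_lo = int(starts[2 + 2 * c])
        segs.append(dict(lo=g_lo, hi=g_lo + seg_len, fold=cfg.cnv_gain_fold, subclone=c))
        segs.append(dict(lo=l_lo, hi=l_lo + seg_len, fold=cfg.cnv_loss_fold, subclone=c))
    _check_segment_conflicts(segs)

    n_ref, n_mal = cfg.n_reference_cells, cfg.n_malignant_cells
    subclone = np.repeat(np.arange(cfg.n_subclones), int(np.ceil(n_mal / cfg.n_subclones)))[:n_mal]
    base = rng.lognormal(np.log(1.0), 0.4, size=n_genes)
    mean = np.tile(base, (n_ref + n_mal, 1))
    for seg in segs:
        rows = (
            np.arange(n_ref, n_ref + n_mal)
            if seg["subclone"] < 0
            else n_ref + np.flatnonzero(subclone == seg["subclone"])
        )
        mean[np.ix_(rows, np.arange(seg["lo"], seg["hi"]))] *= seg["fold"]
    counts = _nb_sample(rng, mean, cfg.nb_theta * 4)
    barcodes = [f"REF{i:04d}" for i in range(n_ref)] + [f"MAL{i:04d}" for i in range(n_mal)]
    cm = CountMatrix(sp.csr_matrix(counts), barcodes, gene_ids, annotation_frame(genes))

    seg_rows = []
    for seg in segs:
        lo_gene, hi_gene = genes[seg["lo"]], genes[seg["hi"] - 1]
        seg_rows.append(
            dict(
                chrom=lo_gene.chrom,
                start=lo_gene.start,
                end=hi_gene.end,
                gene_lo=seg["lo"],
                gene_hi=seg["hi"],
                fold=seg["fold"],
                subclone=seg["subclone"],
            )
        )
    truth = {
        "segments": pd.DataFrame(seg_rows),
        "malignant": pd.Series(
            [False] * n_ref + [True] * n_mal, index=barcodes, name="malignant"
        ),
        "subclone": pd.Series(
            [-1] * n_ref + list(subclone), index=barcodes, name="subclone"
        ),
        "reference_cells": barcodes[:n_ref],
    }
    return cm, truth


def _check_segment_conflicts(segs: list[dict]) -> None:
    for a, b in itertools.combinations(segs, 2):
        same_cells = a["subclone"] == b["subclone"] or -1 in (a["subclone"], b["subclone"])
        overlaps = a["lo"] < b["hi"] and b["lo"] < a["hi"]
        if same_cells and overlaps and a["fold"] != b["fold"]:
            raise ValueError("overlapping segments with conflicting folds")
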
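"""Raw paired reads -> unique-molecule count matrix.

Stages, in read order: trim the RT primer and poly(dA)-tail artifacts from
the insert; slice the 30 nt cell-specific barcode and 8 nt UMI off read 1;
merge observed barcodes onto their acceptor whitelist entries when they are
uniquely within Hamming distance 2 (ambiguous hits are discarded, never
rescued); assign the insert to a gene by exact k-mer voting against the
synthetic transcriptome; collapse (barcode, gene, UMI) triples into
molecule counts.

The 30 nt barcode is corrected as two independent segments (sample
pre-index, droplet barcode) by default, matching the library design; a
single-segment mode treating all 30 nt as one unit is also provided.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .config import BarcodeLayout
from .io import CountMatrix, GeneAnnotation, read_fastq

logger = logging.getLogger("snpipe")

_BASE_TO_INT = {c: i for i, c in enumerate("ACGTN")}


# ---------------------------------------------------------------------------
# trimming and R1 parsing


def trim_insert(seq: str, layout: BarcodeLayout) -> tuple[str, bool]:
    """Remove the leading primer (if present with <= 1 mismatch, no indels)
    and a trailing run of >= ``min_dA_run`` A's.

    Returns (trimmed, too_short); non-matching reads pass through unchanged.
    """
    primer = layout.primer
    if len(seq) >= len(primer):
        mismatches = sum(a != b for a, b in zip(seq, primer))
        if mismatches <= 1:
            seq = seq[len(primer) :]
    n_a = len(seq) - len(seq.rstrip("A"))
    if n_a >= layout.min_dA_run:
        seq = seq[: len(seq) - n_a]
    return seq, len(seq) == 0


def parse_r1(seq: str, layout: BarcodeLayout) -> tuple[str, str] | None:
    """Slice (30 nt barcode, 8 nt UMI) off read 1; None if the read is too
    short. Bases beyond barcode + UMI are ignored."""
    if len(seq) < layout.r1_min_len:
        return None
    bc_len = layout.barcode_len
    return seq[:bc_len], seq[bc_len : bc_len + layout.umi_len]


# ---------------------------------------------------------------------------
# barcode correction


@dataclass(frozen=True)
class CorrectionResult:
    """Outcome of matching one observed barcode against a whitelist."""

    status: str  # exact | corrected | ambiguous | unmatched
    acceptor: str | None
    distance: int

    def __post_init__(self) -> None:
        if self.status == "exact" and self.distance != 0:
            raise ValueError("exact match must have distance 0")
        if self.status in ("ambiguous", "unmatched") and self.acceptor is not None:
            raise ValueError(f"{self.status} result cannot carry an acceptor")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


class BarcodeCorrector:
    """Hamming-distance correction of observed barcodes onto a whitelist.

    An observed sequence is ``exact`` on a whitelist hit, ``corrected`` when
    exactly one whitelist entry lies within ``max_hamming`` substitutions,
    ``ambiguous`` when two or more do, and ``unmatched`` otherwise. The
    whitelist is held as a byte matrix so the distance scan is a single
    vectorized comparison per query.
    """

    def __init__(self, whitelist: Iterable[str], max_hamming: int = 2):
        self.whitelist = list(whitelist)
        if not self.whitelist:
            raise ValueError("empty whitelist")
        lengths = {len(w) for w in self.whitelist}
        if len(lengths) != 1:
            raise ValueError("whitelist entries must all have the same length")
        self.length = lengths.pop()
        self.max_hamming = max_hamming
        self._exact = {w: i for i, w in enumerate(self.whitelist)}
        self._mat = np.vstack([_encode(w) for w in self.whitelist])
        self._cache: dict[str, CorrectionResult] = {}

    def correct(self, observed: str) -> CorrectionResult:
        if len(observed) != self.length:
            raise ValueError(
                f"observed barcode length {len(observed)} != whitelist length {self.length}"
            )
        if observed in self._exact:
            return CorrectionResult("exact", observed, 0)
        hit = self._cache.get(observed)
        if hit is not None:
            return hit
        dists = (self._mat != _encode(observed)).sum(axis=1)
        dmin = int(dists.min())
        result: CorrectionResult
        if dmin > self.max_hamming:
            result = CorrectionResult("unmatched", None, dmin)
        else:
            winners = np.flatnonzero(dists == dmin)
            within = int((dists <= self.max_hamming).sum())
            if within > 1:
                result = CorrectionResult("ambiguous", None, dmin)
            else:
                result = CorrectionResult("corrected", self.whitelist[int(winners[0])], dmin)
        self._cache[observed] = result
        return result


def correct_barcode(
    observed: str, whitelist: Iterable[str], max_hamming: int = 2
) -> CorrectionResult:
    """One-shot form of :class:`BarcodeCorrector` for single queries."""
    return BarcodeCorrector(whitelist, max_hamming).correct(observed)


class SegmentedCorrector:
    """Correct the 30 nt barcode as pre-index + droplet segments.

    Each segment is corrected independently at the shared Hamming budget
    with the unique-acceptor rule; statuses combine conservatively
    (any unmatched -> unmatched, else any ambiguous -> ambiguous)."""

    def __init__(self, layout: BarcodeLayout, preindexes: Iterable[str], droplets: Iterable[str]):
        self.layout = layout
        self.pre = BarcodeCorrector(preindexes, layout.max_hamming)
        self.drop = BarcodeCorrector(droplets, layout.max_hamming)

    def correct(self, barcode30: str) -> CorrectionResult:
        p = self.pre.correct(barcode30[: self.layout.preindex_len])
        d = self.drop.correct(barcode30[self.layout.preindex_len :])
        statuses = {p.status, d.status}
        if "unmatched" in statuses:
            return CorrectionResult("unmatched", None, p.distance + d.distance)
        if "ambiguous" in statuses:
            return CorrectionResult("ambiguous", None, p.distance + d.distance)
        if statuses == {"exact"}:
            return CorrectionResult("exact", p.acceptor + d.acceptor, 0)
        return CorrectionResult("corrected", p.acceptor + d.acceptor, p.distance + d.distance)


# ---------------------------------------------------------------------------
# toy gene assignment


class KmerIndex:
    """Exact k-mer -> gene lookup over a synthetic transcriptome.

    Only valid when no k-mer is shared between genes (the transcriptome
    simulator guarantees this by rejection sampling), which makes every
    error-free vote unanimous.
    """

    def __init__(self, sequences: dict[str, str], k: int = 31):
        self.k = k
        self._index: dict[str, str] = {}
        for gene_id, seq in sequences.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                prev = self._index.get(kmer)
                if prev is not None and prev != gene_id:
                    raise ValueError(f"k-mer shared between {prev} and {gene_id}")
                self._index[kmer] = gene_id

    def assign(self, insert: str, stride: int = 8) -> str:
        """Vote k-mers of the insert (sampled every ``stride`` bases) and
        return the unique winning gene, ``"multimapped"`` on a tie across
        genes, or ``"unmapped"`` with no hits or an insert shorter than k."""
        if len(insert) < self.k:
            return "unmapped"
        votes: Counter[str] = Counter()
        idx = self._index
        for i in range(0, len(insert) - self.k + 1, stride):
            hit = idx.get(insert[i : i + self.k])
            if hit is not None:
                votes[hit] += 1
        if not votes:
            return "unmapped"
        if len(votes) == 1:
            return next(iter(votes))
        (g1, c1), (_, c2) = votes.most_common(2)
        return g1 if c1 > c2 else "multimapped"


def assign_read_to_gene(insert: str, index: KmerIndex, stride: int = 8) -> str:
    return index.assign(insert, stride=stride)


# ---------------------------------------------------------------------------
# UMI counting


def count_umis(
    assignments: Iterable[tuple[str, str, str]], gene_order: Sequence[str]
) -> CountMatrix:
    """Collapse an (acceptor barcode, UMI, gene) stream into molecule counts.

    count(cell, gene) = number of distinct UMI sequences seen for that pair;
    identical triples collapse to one molecule. UMIs are scoped per cell, so
    the same sequence in two cells counts in both. No UMI error correction
    is applied (exact deduplication).
    """
    triples = set(assignments)
    df = pd.DataFrame(triples, columns=["barcode", "umi", "gene_id"])
    if df.empty:
        return CountMatrix(
            np.zeros((0, len(gene_order)), dtype=np.int64), [], list(gene_order)
        )
    counts = df.groupby(["barcode", "gene_id"]).size()
    barcodes = sorted(df["barcode"].unique())
    b_idx = {b: i for i, b in enumerate(barcodes)}
    g_idx = {g: i for i, g in enumerate(gene_order)}
    import scipy.sparse as sp

    rows = [b_idx[b] for b, _ in counts.index]
    cols = [g_idx[g] for _, g in counts.index]
    mat = sp.csr_matrix(
        (counts.to_numpy(), (rows, cols)), shape=(len(barcodes), len(gene_order))
    )
    return CountMatrix(mat, barcodes, list(gene_order))


# ---------------------------------------------------------------------------
# end-to-end demultiplexing


def demux(
    r1_path: str | Path,
    r2_path: str | Path,
    layout: BarcodeLayout,
    preindex_whitelist: Sequence[str],
    droplet_whitelist: Sequence[str],
    genes: list[GeneAnnotation],
    sequences: dict[str, str],
    kmer_stride: int = 8,
    audit_path: str | Path | None = None,
) -> tuple[CountMatrix, dict[str, int]]:
    """Run the full read pipeline on a FASTQ pair.

    Returns the molecule count matrix (barcodes sorted, genes in annotation
    order) and the per-category read accounting, which always conserves:
    reads in = assigned + too_short + unmatched + ambiguous + unmapped +
    multimapped.
    """
    if layout.two_segment:
        corrector = SegmentedCorrector(layout, preindex_whitelist, droplet_whitelist)
    else:
        full = [p + d for p in preindex_whitelist for d in droplet_whitelist]
        corrector = BarcodeCorrector(full, layout.max_hamming)  # type: ignore[assignment]
    index = KmerIndex(sequences, k=31)

    stats: Counter[str] = Counter()
    triples: list[tuple[str, str, str]] = []
    audit_rows: list[tuple[str, str, int]] = []
    for (name1, seq1), (name2, seq2) in zip(read_fastq(r1_path), read_fastq(r2_path)):
        stats["reads_in"] += 1
        parsed = parse_r1(seq1, layout)
        if parsed is None:
            stats["too_short"] += 1
            audit_rows.append((name1, "too_short", -1))
            continue
        barcode30, umi = parsed
        res = corrector.correct(barcode30)
        if res.status in ("ambiguous", "unmatched"):
            stats[res.status] += 1
            audit_rows.append((name1, res.status, res.distance))
            continue
        insert, too_short = trim_insert(seq2, layout)
        if too_short:
            stats["too_short"] += 1
            audit_rows.append((name1, "too_short", res.distance))
            continue
        gene = index.assign(insert, stride=kmer_stride)
        if gene in ("unmapped", "multimapped"):
            stats[gene] += 1
            audit_rows.append((name1, gene, res.distance))
            continue
        stats["assigned"] += 1
        audit_rows.append((name1, res.status, res.distance))
        triples.append((res.acceptor, umi, gene))

    matrix = count_umis(triples, [g.gene_id for g in genes])
    if audit_path is not None:
        pd.DataFrame(audit_rows, columns=["read_id", "status", "distance"]).to_csv(
            audit_path, sep="\t", index=False
        )
    logger.info("demux accounting: %s", json.dumps(dict(stats)))
    return matrix, dict(stats)
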
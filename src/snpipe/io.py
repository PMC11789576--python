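"""Readers and writers for the standard formats the pipeline touches.

Coordinate convention: GTF on disk is 1-based inclusive; everything in
memory uses 0-based half-open intervals. The converters in this module are
the only place the shift happens.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

BIOTYPES = ("protein_coding", "lncRNA", "snoRNA", "snRNA", "miRNA", "other")

#: default mapping of GTF biotype strings onto the canonical set
DEFAULT_BIOTYPE_ALIASES: Mapping[str, str] = {
    "lincRNA": "lncRNA",
    "antisense": "lncRNA",
    "protein_coding": "protein_coding",
    "lncRNA": "lncRNA",
    "snoRNA": "snoRNA",
    "snRNA": "snRNA",
    "miRNA": "miRNA",
}

#: symbol prefixes that mark a gene as mitochondrial (per species convention)
DEFAULT_MITO_PREFIXES = ("MT-", "mt-")


class GtfParseError(ValueError):
    """Raised when a GTF record cannot be parsed; message names the line."""


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: identity, biotype, barnyard species label and locus.

    ``start``/``end`` are 0-based half-open (converted from the 1-based
    inclusive coordinates GTF uses on disk).
    """

    gene_id: str
    symbol: str
    biotype: str
    species: str  # barnyard label, "A" or "B"
    chrom: str
    start: int
    end: int
    mito: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.gene_id}: unknown biotype {self.biotype!r}")


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(
    path: str | Path,
    biotype_aliases: Mapping[str, str] | None = None,
    mito_prefixes: Iterable[str] = DEFAULT_MITO_PREFIXES,
) -> list[GeneAnnotation]:
    """Read gene-level records from a GTF file.

    Unknown biotypes map to ``"other"``; a ``biotype_aliases`` table (for
    example ``{"lincRNA": "lncRNA"}``) is applied first. The barnyard
    species label is taken from a ``species`` attribute when present and
    defaults to ``"A"``. Raises :class:`GtfParseError` naming the offending
    line on malformed records.
    """
    aliases = dict(DEFAULT_BIOTYPE_ALIASES)
    if biotype_aliases:
        aliases.update(biotype_aliases)
    mito_prefixes = tuple(mito_prefixes)
    opener = gzip.open if str(path).endswith(".gz") else open
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
            if fields[2] != "gene":
                continue
            attrs = _parse_attributes(fields[8])
            if "gene_id" not in attrs:
                raise GtfParseError(f"line {lineno}: gene record missing gene_id attribute")
            gene_id = attrs["gene_id"]
            if gene_id in seen:
                raise GtfParseError(f"line {lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            raw_biotype = attrs.get("gene_biotype", attrs.get("gene_type", "other"))
            biotype = aliases.get(raw_biotype, raw_biotype)
            if biotype not in BIOTYPES:
                biotype = "other"
            symbol = attrs.get("gene_name", gene_id)
            try:
                start_1based, end_1based = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
            genes.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    symbol=symbol,
                    biotype=biotype,
                    species=attrs.get("species", "A"),
                    chrom=fields[0],
                    start=start_1based - 1,  # 1-based inclusive -> 0-based half-open
                    end=end_1based,
                    mito=symbol.startswith(mito_prefixes),
                )
            )
    return genes


def write_gtf(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    """Write gene-level GTF records (1-based inclusive coordinates on disk)."""
    with open(path, "wt") as fh:
        for g in genes:
            attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.symbol}"; '
                f'gene_biotype "{g.biotype}"; species "{g.species}";'
            )
            fh.write(
                f"{g.chrom}\tsnpipe\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\t{attrs}\n"
            )


def annotation_frame(genes: Iterable[GeneAnnotation]) -> pd.DataFrame:
    """Tabulate annotations as a DataFrame indexed by gene_id."""
    df = pd.DataFrame([vars(g) for g in genes])
    return df.set_index("gene_id", drop=False)


@dataclass
class CountMatrix:
    """Nuclei x genes unique-molecule counts with aligned label vectors.

    ``matrix`` is a sparse CSR of shape (n_barcodes, n_genes); ``var`` is an
    optional per-gene annotation table aligned to ``genes``.
    """

    matrix: sp.csr_matrix
    barcodes: list[str]
    genes: list[str]
    var: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.barcodes), len(self.genes)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.genes)} genes"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcode labels")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene labels")
        if self.var is not None:
            self.var = self.var.reindex(self.genes)

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())

    def subset(self, barcode_mask=None, gene_mask=None) -> "CountMatrix":
        """Row/column subset by boolean mask or index array; labels follow."""
        m = self.matrix
        barcodes, genes, var = self.barcodes, self.genes, self.var
        if barcode_mask is not None:
            idx = np.asarray(barcode_mask)
            if idx.dtype == bool:
                idx = np.flatnonzero(idx)
            m = m[idx]
            barcodes = [barcodes[i] for i in idx]
        if gene_mask is not None:
            idx = np.asarray(gene_mask)
            if idx.dtype == bool:
                idx = np.flatnonzero(idx)
            m = m[:, idx]
            genes = [genes[i] for i in idx]
            if var is not None:
                var = var.iloc[idx]
        return CountMatrix(sp.csr_matrix(m), barcodes, genes, var)

    # --- MatrixMarket round-trip -------------------------------------------

    def write_mtx(self, outdir: str | Path) -> None:
        """Write matrix.mtx + features.tsv + barcodes.tsv (cells as columns,
        the layout 10x-style tools expect)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(self.matrix.T))
        pd.Series(self.genes).to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
        pd.Series(self.barcodes).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
        if self.var is not None:
            self.var.to_csv(outdir / "features_meta.tsv", sep="\t", index=True)

    @classmethod
    def read_mtx(cls, indir: str | Path) -> "CountMatrix":
        indir = Path(indir)
        mat = sp.csr_matrix(scipy.io.mmread(str(indir / "matrix.mtx")).T)
        genes = _read_label_column(indir / "features.tsv")
        barcodes = _read_label_column(indir / "barcodes.tsv")
        var = None
        meta = indir / "features_meta.tsv"
        if meta.exists():
            var = pd.read_csv(meta, sep="\t", index_col=0)
        return cls(mat, barcodes, genes, var)


def _read_label_column(path: Path) -> list[str]:
    if path.stat().st_size == 0:
        return []
    return pd.read_csv(path, sep="\t", header=None)[0].astype(str).tolist()


def read_fastq(path: str | Path):
    """Yield (name, sequence) pairs from a possibly gzipped FASTQ file."""
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            yield rec.name, rec.sequence


class FastqWriter:
    """Minimal gzipped FASTQ writer with a constant quality string."""

    def __init__(self, path: str | Path, quality_char: str = "F"):
        self._fh = gzip.open(path, "wt")
        self._q = quality_char

    def write(self, name: str, seq: str) -> None:
        self._fh.write(f"@{name}\n{seq}\n+\n{self._q * len(seq)}\n")

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "FastqWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()
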
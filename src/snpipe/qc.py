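"""Cell calling from the barcode rank curve, barnyard statistics, QC filters.

The knee rule: barcodes are ordered by detected genes (rank 1 = most); the
calling threshold sits at the steepest descent of the smoothed
log10(genes) vs log10(rank) curve — the cliff that separates
nuclei-containing barcodes from ambient background. The raw curve is
always emitted alongside the call so any alternative rule can be audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.signal

from .io import CountMatrix

logger = logging.getLogger("snpipe")


class NoKneeError(ValueError):
    """The rank curve has no detectable cliff (max |slope| below tolerance)."""


@dataclass
class CellCallResult:
    threshold: float  # gene-count threshold; called = genes strictly above
    called: set[str]
    curve: pd.DataFrame  # barcode, genes_detected, rank (descending genes)


def call_cells(
    genes_per_barcode: Mapping[str, int],
    smooth_window: int = 21,
    slope_tol: float = 1.0,
) -> CellCallResult:
    """Call nuclei-containing barcodes at the knee of the rank curve.

    The smoothed first derivative of log10(genes) with respect to
    log10(rank) is minimized (steepest descent); the gene count at that
    position is the threshold and barcodes strictly above it are called.
    Raises :class:`NoKneeError` on flat curves.
    """
    if len(genes_per_barcode) < 100:
        raise ValueError("need at least 100 barcodes with nonzero genes")
    curve = (
        pd.DataFrame(
            {"barcode": list(genes_per_barcode), "genes_detected": list(genes_per_barcode.values())}
        )
        .sort_values(["genes_detected", "barcode"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    if (curve["genes_detected"] <= 0).any():
        raise ValueError("all barcodes must have nonzero detected genes")
    curve["rank"] = np.arange(1, len(curve) + 1)
    x = np.log10(curve["rank"].to_numpy(dtype=float))
    y = np.log10(curve["genes_detected"].to_numpy(dtype=float))
    # resample onto an even log-rank grid: raw ranks crowd the tail, which
    # would otherwise dominate the derivative through tiny x-spacing
    n_grid = 512
    xg = np.linspace(x[0], x[-1], n_grid)
    yg = np.interp(xg, x, y)
    window = min(smooth_window, n_grid - 1)
    window -= 1 - window % 2  # odd
    if window >= 3:
        yg = scipy.signal.savgol_filter(yg, window_length=window, polyorder=1)
    slope = np.gradient(yg, xg)
    if np.abs(slope).max() < slope_tol:
        raise NoKneeError(f"no knee detected: max |slope| {np.abs(slope).max():.3g} < {slope_tol}")
    knee = int(np.argmin(slope))
    # threshold from the smoothed curve: mid-cliff this sits between the
    # plateaus instead of snapping to either raw value at the knee index
    threshold = float(10 ** yg[knee])
    called = set(curve.loc[curve["genes_detected"] > threshold, "barcode"])
    logger.info(
        "call_cells: threshold=%g called=%d of %d barcodes", threshold, len(called), len(curve)
    )
    return CellCallResult(threshold=threshold, called=called, curve=curve)


@dataclass
class SpeciesMixStats:
    per_barcode: pd.DataFrame  # umis_A, umis_B, purity, call
    doublet_rate: float
    n_called: int

    @property
    def n_doublets(self) -> int:
        return int((self.per_barcode["call"] == "doublet").sum())


def species_mix(
    matrix: CountMatrix,
    purity_min: float = 0.90,
    extrapolate: bool = False,
) -> SpeciesMixStats:
    """Barnyard purity and doublet statistics over called barcodes.

    A barcode is a doublet iff its purity — the larger species fraction of
    its UMIs — falls below ``purity_min``. The reported rate is the observed
    cross-species rate; ``extrapolate`` doubles it to include the
    unobservable same-species collisions.
    """
    if matrix.var is None or "species" not in matrix.var:
        raise ValueError("matrix must carry a per-gene species annotation")
    species = matrix.var["species"].to_numpy()
    present = set(species)
    if not {"A", "B"} <= present:
        raise ValueError("barnyard statistics need genes from both species")
    umis_a = np.asarray(matrix.matrix[:, species == "A"].sum(axis=1)).ravel()
    umis_b = np.asarray(matrix.matrix[:, species == "B"].sum(axis=1)).ravel()
    total = umis_a + umis_b
    with np.errstate(invalid="ignore", divide="ignore"):
        purity = np.maximum(umis_a, umis_b) / total
    call = np.where(
        purity < purity_min, "doublet", np.where(umis_a >= umis_b, "species_A", "species_B")
    )
    per_barcode = pd.DataFrame(
        {"umis_A": umis_a, "umis_B": umis_b, "purity": purity, "call": call},
        index=matrix.barcodes,
    )
    n_doublets = int((call == "doublet").sum())
    rate = n_doublets / len(call) if len(call) else 0.0
    if extrapolate:
        rate *= 2.0
    return SpeciesMixStats(per_barcode=per_barcode, doublet_rate=rate, n_called=len(call))


def qc_filter(
    matrix: CountMatrix, min_genes: int = 200, min_cells: int = 3
) -> tuple[CountMatrix, dict[str, int]]:
    """Drop nuclei with fewer than ``min_genes`` detected genes, then genes
    detected in fewer than ``min_cells`` of the remaining nuclei (in that
    order). Returns the filtered matrix and the removal accounting."""
    genes_per_cell = np.asarray((matrix.matrix > 0).sum(axis=1)).ravel()
    cell_keep = genes_per_cell >= min_genes
    step1 = matrix.subset(barcode_mask=cell_keep)
    cells_per_gene = np.asarray((step1.matrix > 0).sum(axis=0)).ravel()
    gene_keep = cells_per_gene >= min_cells
    out = step1.subset(gene_mask=gene_keep)
    stats = {
        "cells_removed": int((~cell_keep).sum()),
        "genes_removed": int((~gene_keep).sum()),
        "cells_kept": out.shape[0],
        "genes_kept": out.shape[1],
    }
    if out.shape[0] == 0 or out.shape[1] == 0:
        raise ValueError(f"qc_filter removed everything: {stats}")
    logger.info("qc_filter: %s (min_genes=%d, min_cells=%d)", stats, min_genes, min_cells)
    return out, stats


def mito_fraction(matrix: CountMatrix, annotation: pd.DataFrame) -> pd.Series:
    """Per-nucleus fraction of UMIs from mitochondrial genes.

    Nuclei with zero UMIs get NaN (undefined) and are logged.
    """
    mito = annotation["mito"].reindex(matrix.genes).fillna(False).to_numpy(dtype=bool)
    mito_umis = np.asarray(matrix.matrix[:, mito].sum(axis=1)).ravel()
    total = np.asarray(matrix.matrix.sum(axis=1)).ravel()
    frac = np.full(len(total), np.nan)
    nz = total > 0
    frac[nz] = mito_umis[nz] / total[nz]
    if (~nz).any():
        logger.warning("%d nuclei with zero UMIs: mito fraction undefined", int((~nz).sum()))
    return pd.Series(frac, index=matrix.barcodes, name="mito_fraction")
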
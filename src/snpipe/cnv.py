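"""Per-cell CNV estimation, scoring, malignant calling and subclones.

The windowed estimator is a deliberately simple stand-in for full CNV
callers: genes are ordered along the genome, each cell's expression
residual against a diploid reference is clipped and averaged in a moving
window per chromosome, giving a cells x regions matrix of relative
copy-number deviations (0 = neutral). The per-cell CNV score is the
quadratic sum of the region values, and the score/subclone stages accept
externally produced CNV matrices (e.g. from a dedicated caller) through
the TSV importer so they are agnostic to region provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy

from .expression import CountMatrix

logger = logging.getLogger("snpipe")


@dataclass
class CNVMatrix:
    """Cells x genomic regions relative copy-number deviations."""

    cells: list[str]
    regions: pd.DataFrame  # chrom, start, end (sorted within chromosome)
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.cells), len(self.regions)):
            raise ValueError("values shape does not match cells x regions")
        if not np.isfinite(self.values).all():
            raise ValueError("CNV values must be finite")
        for _, grp in self.regions.groupby("chrom", sort=False):
            if not grp["start"].is_monotonic_increasing:
                raise ValueError("regions must be sorted by position within chromosome")

    def to_tsv(self, path: str | Path) -> None:
        cols = [f"{r.chrom}:{r.start}-{r.end}" for r in self.regions.itertuples()]
        pd.DataFrame(self.values, index=self.cells, columns=cols).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CNVMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        parts = [c.replace("-", ":").split(":") for c in df.columns]
        regions = pd.DataFrame(
            {"chrom": [p[0] for p in parts],
             "start": [int(p[1]) for p in parts],
             "end": [int(p[2]) for p in parts]}
        )
        return cls(list(df.index), regions, df.to_numpy())

    def subset_cells(self, cells: Sequence[str]) -> "CNVMatrix":
        idx = {c: i for i, c in enumerate(self.cells)}
        rows = [idx[c] for c in cells]
        return CNVMatrix(list(cells), self.regions, self.values[rows])


def windowed_cnv_estimate(
    normalized: CountMatrix,
    annotation: pd.DataFrame,
    reference_cells: Sequence[str],
    window: int = 101,
) -> CNVMatrix:
    """Moving-average CNV estimate against a diploid reference.

    Genes are ordered by genomic position; per-gene expression residuals
    (cell value minus reference mean, clipped to +/- 3 reference SDs) are
    averaged in a centred window of ``window`` genes within each
    chromosome. Chromosomes with fewer genes than the window use the whole
    chromosome (warned). One region per gene position is emitted.
    """
    if not reference_cells:
        raise ValueError("reference cell set is empty")
    ann = annotation.reindex(normalized.genes)
    if ann[["chrom", "start"]].isna().any().any():
        raise ValueError("every gene needs genomic coordinates")
    order = np.lexsort((ann["start"].to_numpy(), ann["chrom"].to_numpy()))
    m = normalized.subset(gene_mask=order)
    ann = ann.iloc[order]

    dense = m.to_dense()
    ref_idx = [m.barcodes.index(c) for c in reference_cells]
    ref = dense[ref_idx]
    ref_mean = ref.mean(axis=0)
    ref_sd = ref.std(axis=0, ddof=0)
    floor = max(np.median(ref_sd), 1e-6)  # guard near-silent genes
    clip = 3.0 * np.maximum(ref_sd, floor)
    resid = np.clip(dense - ref_mean, -clip, clip)

    values = np.empty_like(resid)
    chroms = ann["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        w = min(window, len(cols))
        if w < window:
            logger.warning("chromosome %s has %d genes < window %d; window shrunk", chrom, len(cols), window)
        if w % 2 == 0:
            w = max(w - 1, 1)
        half = w // 2
        block = resid[:, cols]
        csum = np.cumsum(np.pad(block, ((0, 0), (1, 0))), axis=1)
        n = len(cols)
        lo = np.maximum(np.arange(n) - half, 0)
        hi = np.minimum(np.arange(n) + half + 1, n)
        values[:, cols] = (csum[:, hi] - csum[:, lo]) / (hi - lo)
    regions = pd.DataFrame(
        {"chrom": chroms, "start": ann["start"].to_numpy(), "end": ann["end"].to_numpy()}
    )
    return CNVMatrix(list(m.barcodes), regions, values)


def cnv_score(matrix: CNVMatrix) -> pd.Series:
    """Per-cell CNV score: the quadratic sum over regions, sum_r value^2."""
    return pd.Series((matrix.values**2).sum(axis=1), index=matrix.cells, name="cnv_score")


def classify_malignant(
    scores: pd.Series, method: str = "2-means", reference_scores: pd.Series | None = None
) -> pd.Series:
    """Split cells into malignant/diploid by CNV score.

    ``"2-means"``: deterministic 1-D 2-means initialized at the score min
    and max; the higher-mean group is malignant. ``"3sd"``: malignant iff
    score > mean + 3 SD of the reference scores (the score population
    itself when no reference is given). Degenerate inputs (all scores
    equal) yield all-diploid with a warning.
    """
    if len(scores) < 10:
        raise ValueError("need at least 10 cells")
    x = scores.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        logger.warning("classify_malignant: all scores equal; labelling all diploid")
        return pd.Series("diploid", index=scores.index, name="call")
    if method == "2-means":
        c_lo, c_hi = float(x.min()), float(x.max())
        for _ in range(100):
            assign = np.abs(x - c_lo) <= np.abs(x - c_hi)  # True -> low cluster
            new_lo = x[assign].mean() if assign.any() else c_lo
            new_hi = x[~assign].mean() if (~assign).any() else c_hi
            if new_lo == c_lo and new_hi == c_hi:
                break
            c_lo, c_hi = new_lo, new_hi
        malignant = ~assign
    elif method == "3sd":
        ref = reference_scores.to_numpy(dtype=float) if reference_scores is not None else x
        malignant = x > ref.mean() + 3.0 * ref.std(ddof=0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.Series(
        np.where(malignant, "malignant", "diploid"), index=scores.index, name="call"
    )


@dataclass
class SubcloneResult:
    labels: pd.Series  # subclone id per malignant cell
    profiles: pd.DataFrame  # subclone x region mean CNV
    gain_loss: pd.DataFrame  # subclone x region in {-1, 0, +1}
    composition: pd.DataFrame | None  # subclone x cluster counts (if given)
    proportions_by_timepoint: pd.DataFrame | None


def subclone_cluster(
    matrix: CNVMatrix,
    k: int,
    cluster_labels: pd.Series | None = None,
    timepoints: pd.Series | None = None,
    gain_loss_threshold: float = 0.05,
) -> SubcloneResult:
    """Partition malignant cells into ``k`` subclones by Ward clustering.

    Hierarchical clustering (Euclidean distance, Ward linkage) on the CNV
    matrix, cut at ``k``; emits per-subclone mean profiles, gain/loss calls
    (mean above +t or below -t), cluster composition, and per-timepoint
    subclone proportions when a timepoint covariate is supplied.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(matrix.cells):
        raise ValueError(f"k={k} exceeds {len(matrix.cells)} cells")
    linkage = scipy.cluster.hierarchy.linkage(matrix.values, method="ward")
    raw = scipy.cluster.hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    # relabel subclones in cell order for a deterministic, order-free naming
    relabel: dict[int, int] = {}
    for r in raw:
        if r not in relabel:
            relabel[r] = len(relabel) + 1
    labels = pd.Series([f"subclone{relabel[r]}" for r in raw], index=matrix.cells, name="subclone")

    profiles = (
        pd.DataFrame(matrix.values, index=matrix.cells)
        .groupby(labels)
        .mean()
    )
    gain_loss = pd.DataFrame(
        np.sign(profiles.to_numpy()) * (np.abs(profiles.to_numpy()) > gain_loss_threshold),
        index=profiles.index,
        columns=profiles.columns,
    ).astype(int)
    composition = None
    if cluster_labels is not None:
        composition = (
            pd.crosstab(labels, cluster_labels.reindex(matrix.cells))
        )
    proportions = None
    if timepoints is not None:
        tab = pd.crosstab(timepoints.reindex(matrix.cells), labels)
        proportions = tab.div(tab.sum(axis=1), axis=0)
    return SubcloneResult(labels, profiles, gain_loss, composition, proportions)
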
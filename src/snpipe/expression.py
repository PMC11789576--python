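"""Normalization, variable genes, cluster profiles, module scores, markers.

Normalization is library-size log1p scaling: a deliberate simplification
that preserves rank-based downstream results (markers, correlations,
variable-gene order) while keeping absolute values simple to reason about.
Clustering itself is consumed as externally provided labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .io import BIOTYPES, CountMatrix

logger = logging.getLogger("snpipe")


def normalize_log(matrix: CountMatrix, scale: float = 1e4) -> CountMatrix:
    """log(1 + scale * count / cell_total); zeros stay zero (sparse).

    Raises on zero-total cells — those should have been removed by
    ``qc_filter`` before normalization.
    """
    m = sp.csr_matrix(matrix.matrix, dtype=np.float64)
    totals = np.asarray(m.sum(axis=1)).ravel()
    if (totals == 0).any():
        bad = [matrix.barcodes[i] for i in np.flatnonzero(totals == 0)[:5]]
        raise ValueError(f"zero-total cells present (e.g. {bad}); run qc_filter first")
    scaled = sp.diags(scale / totals) @ m
    scaled.data = np.log1p(scaled.data)
    return CountMatrix(scaled, list(matrix.barcodes), list(matrix.genes), matrix.var)


def gene_variance(matrix: CountMatrix) -> np.ndarray:
    """Per-gene variance across cells, computed sparsely as E[x^2]-E[x]^2."""
    m = matrix.matrix
    n = m.shape[0]
    mean = np.asarray(m.mean(axis=0)).ravel()
    mean_sq = np.asarray(m.multiply(m).mean(axis=0)).ravel()
    return np.maximum(mean_sq - mean**2, 0.0) * n / max(n - 1, 1)


def select_hvg(matrix: CountMatrix, n: int = 2000) -> list[str]:
    """Top-n genes by variance of normalized expression; ties broken by
    lexicographic gene id so the selection is deterministic."""
    if n > len(matrix.genes):
        raise ValueError(f"requested {n} HVGs from {len(matrix.genes)} genes")
    var = gene_variance(matrix)
    order = sorted(range(len(matrix.genes)), key=lambda i: (-var[i], matrix.genes[i]))
    return [matrix.genes[i] for i in order[:n]]


@dataclass
class ClusterProfile:
    """Gene x cluster matrix of mean normalized expression."""

    genes: list[str]
    clusters: list
    values: np.ndarray  # genes x clusters

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.genes), len(self.clusters)):
            raise ValueError("profile shape does not match labels")
        if not np.isfinite(self.values).all():
            raise ValueError("profile contains non-finite values")

    def subset_genes(self, keep: list[str]) -> "ClusterProfile":
        idx = {g: i for i, g in enumerate(self.genes)}
        rows = [idx[g] for g in keep]
        return ClusterProfile(list(keep), list(self.clusters), self.values[rows])


def cluster_profile(
    matrix: CountMatrix, labels: pd.Series, genes: list[str] | None = None
) -> ClusterProfile:
    """Mean normalized expression per (gene, cluster); cluster order is the
    sorted label order. Every cell must be labeled; empty clusters are an
    error and singleton clusters warn."""
    labels = labels.reindex(matrix.barcodes)
    if labels.isna().any():
        raise ValueError("every cell must carry a cluster label")
    clusters = sorted(labels.unique())
    genes = genes if genes is not None else list(matrix.genes)
    sub = matrix.subset(gene_mask=[matrix.genes.index(g) for g in genes])
    values = np.empty((len(genes), len(clusters)))
    for j, cl in enumerate(clusters):
        mask = (labels == cl).to_numpy()
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"empty cluster {cl!r}")
        if n == 1:
            logger.warning("singleton cluster %r", cl)
        values[:, j] = np.asarray(sub.matrix[mask].mean(axis=0)).ravel()
    return ClusterProfile(list(genes), clusters, values)


def module_score(
    matrix: CountMatrix,
    gene_set: list[str],
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell gene-set score against expression-matched controls.

    Genes are binned by their average expression across cells into
    ``n_bins`` equal-size bins; for each set gene, ``n_ctrl`` control genes
    are drawn (with replacement) from its bin, excluding set genes. The
    score is mean(set genes) - mean(control draw) per cell, so a set behaving
    like the background is centred at zero.
    """
    rng = np.random.default_rng(seed)
    gene_pos = {g: i for i, g in enumerate(matrix.genes)}
    set_idx = [gene_pos[g] for g in gene_set if g in gene_pos]
    if not set_idx:
        raise ValueError("gene set has empty intersection with the matrix")
    avg = np.asarray(matrix.matrix.mean(axis=0)).ravel()
    # equal-occupancy bins over the rank of average expression
    order = np.argsort(avg, kind="stable")
    bin_of = np.empty(len(avg), dtype=np.int64)
    bin_of[order] = np.minimum(
        (np.arange(len(avg)) * n_bins) // len(avg), n_bins - 1
    )
    set_mask = np.zeros(len(avg), dtype=bool)
    set_mask[set_idx] = True
    ctrl_idx: list[int] = []
    for gi in set_idx:
        candidates = np.flatnonzero((bin_of == bin_of[gi]) & ~set_mask)
        if len(candidates) == 0:  # degenerate bin: fall back to all non-set genes
            candidates = np.flatnonzero(~set_mask)
        ctrl_idx.extend(rng.choice(candidates, size=n_ctrl, replace=True))
    m = matrix.matrix
    set_mean = np.asarray(m[:, set_idx].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(m[:, ctrl_idx].mean(axis=1)).ravel()
    return pd.Series(set_mean - ctrl_mean, index=matrix.barcodes, name="module_score")


def find_markers(
    matrix: CountMatrix,
    labels: pd.Series,
    only_pos: bool = True,
    min_pct: float = 0.25,
    logfc_min: float = 0.25,
    exact_max_n: int = 20,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker table per cluster.

    Genes are pre-filtered by detection fraction (``min_pct`` in either
    group) and by log fold-change before testing; p-values are
    Benjamini-Hochberg adjusted within each cluster. The rank-sum test uses
    exact enumeration when the comparison involves at most ``exact_max_n``
    cells and the tie-corrected normal approximation otherwise. Log
    fold-change is the difference of mean log-normalized expression.
    """
    labels = labels.reindex(matrix.barcodes)
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    dense = matrix.to_dense()
    rows = []
    for cl in clusters:
        mask = (labels == cl).to_numpy()
        n_in = int(mask.sum())
        if n_in < 3:
            logger.warning("cluster %r has fewer than 3 cells; skipped", cl)
            continue
        x_in, x_out = dense[mask], dense[~mask]
        pct_in = (x_in > 0).mean(axis=0)
        pct_out = (x_out > 0).mean(axis=0)
        logfc = x_in.mean(axis=0) - x_out.mean(axis=0)
        keep = (np.maximum(pct_in, pct_out) >= min_pct) & (
            (logfc >= logfc_min) if only_pos else (np.abs(logfc) >= logfc_min)
        )
        method = "exact" if dense.shape[0] <= exact_max_n else "asymptotic"
        for gi in np.flatnonzero(keep):
            alt = "greater" if only_pos else "two-sided"
            p = scipy.stats.mannwhitneyu(
                x_in[:, gi], x_out[:, gi], alternative=alt, method=method
            ).pvalue
            rows.append(
                dict(
                    gene=matrix.genes[gi],
                    cluster=cl,
                    logfc=float(logfc[gi]),
                    pct_in=float(pct_in[gi]),
                    pct_out=float(pct_out[gi]),
                    pval=float(p),
                )
            )
    table = pd.DataFrame(rows, columns=["gene", "cluster", "logfc", "pct_in", "pct_out", "pval"])
    if table.empty:
        table["padj"] = pd.Series(dtype=float)
        return table
    table["padj"] = np.nan
    for cl in table["cluster"].unique():
        m = table["cluster"] == cl
        table.loc[m, "padj"] = scipy.stats.false_discovery_control(table.loc[m, "pval"])
    table["padj"] = np.maximum(table["padj"], table["pval"])
    return table.sort_values(["cluster", "padj", "gene"]).reset_index(drop=True)


def biotype_counts(matrix: CountMatrix, annotation: pd.DataFrame) -> pd.Series:
    """Detected genes (nonzero in >= 1 retained nucleus) per RNA biotype."""
    detected = np.asarray((matrix.matrix > 0).sum(axis=0)).ravel() > 0
    biotype = annotation["biotype"].reindex(matrix.genes)
    missing = biotype.isna()
    if missing.any():
        logger.warning("%d genes missing annotation; counted as 'other'", int(missing.sum()))
        biotype = biotype.fillna("other")
    counts = (
        pd.Series(biotype.to_numpy()[detected])
        .value_counts()
        .reindex(BIOTYPES, fill_value=0)
    )
    counts.name = "detected_genes"
    return counts
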
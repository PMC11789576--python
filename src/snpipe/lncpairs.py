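"""Cluster-specific lncRNA-mRNA pair discovery (the LncPairs procedure).

Six steps: (1) average the top variable genes over clusters into a
gene x cluster profile; (2) split it by biotype into mRNA and lncRNA
profiles; (3) retain lncRNA-mRNA pairs whose Pearson correlation across
cluster profiles strictly exceeds ``pcc_min``; (4) build a pair x cluster
activity matrix; (5) score each pair's cluster specificity by cosine
similarity against one-hot cluster indicators; (6) eliminate pairs whose
best cosine falls below ``cos_min`` and assign the rest to their argmax
cluster.

The pair x cluster construction is the min-of-minmax rule: each partner's
cluster profile is rescaled to [0, 1] and the pair's activity in a cluster
is the smaller of the two — a pair is active only where both partners are
jointly elevated, and the rule reduces to a one-hot row in the clean
single-cluster case. A product rule is available as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ClusterProfile, cluster_profile, normalize_log, select_hvg
from .io import CountMatrix

logger = logging.getLogger("snpipe")


def split_profile(
    profile: ClusterProfile, annotation: pd.DataFrame
) -> tuple[ClusterProfile, ClusterProfile]:
    """Partition a cluster profile into (mRNA, lncRNA) halves by biotype.

    Genes of other biotypes are dropped (count logged); an empty partition
    is an error because the pairing step would be vacuous.
    """
    biotype = annotation["biotype"].reindex(profile.genes)
    mrna = [g for g, b in zip(profile.genes, biotype) if b == "protein_coding"]
    lnc = [g for g, b in zip(profile.genes, biotype) if b == "lncRNA"]
    dropped = len(profile.genes) - len(mrna) - len(lnc)
    if dropped:
        logger.info("split_profile: dropped %d genes of other biotypes", dropped)
    if not mrna or not lnc:
        raise ValueError(
            f"biotype partition empty: {len(mrna)} protein_coding, {len(lnc)} lncRNA"
        )
    return profile.subset_genes(mrna), profile.subset_genes(lnc)


def correlate_pairs(
    lnc_profile: ClusterProfile,
    mrna_profile: ClusterProfile,
    pcc_min: float = 0.85,
) -> pd.DataFrame:
    """All lncRNA x mRNA pairs with Pearson correlation across cluster
    profiles strictly greater than ``pcc_min``.

    Zero-variance gene rows are skipped (correlation undefined) and logged.
    Returns a table with columns lnc_id, mrna_id, pcc.
    """
    if len(lnc_profile.clusters) < 3:
        raise ValueError("need >= 3 clusters for a meaningful profile correlation")

    def _standardize(p: ClusterProfile) -> tuple[np.ndarray, np.ndarray]:
        v = p.values
        sd = v.std(axis=1, ddof=0)
        ok = sd > 0
        z = np.zeros_like(v)
        z[ok] = (v[ok] - v[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
        return z, ok

    zl, ok_l = _standardize(lnc_profile)
    zm, ok_m = _standardize(mrna_profile)
    skipped = int((~ok_l).sum() + (~ok_m).sum())
    if skipped:
        logger.info("correlate_pairs: %d zero-variance gene rows skipped", skipped)
    k = len(lnc_profile.clusters)
    pcc = (zl @ zm.T) / k
    li, mi = np.nonzero((pcc > pcc_min) & ok_l[:, None] & ok_m[None, :])
    return pd.DataFrame(
        {
            "lnc_id": [lnc_profile.genes[i] for i in li],
            "mrna_id": [mrna_profile.genes[i] for i in mi],
            "pcc": pcc[li, mi],
        }
    )


@dataclass
class PairClusterMatrix:
    pairs: pd.DataFrame  # lnc_id, mrna_id, pcc
    clusters: list
    activity: np.ndarray  # pairs x clusters, values in [0, 1]


def _minmax_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    span = (hi - lo).ravel()
    ok = span > 0
    out = np.zeros_like(values)
    out[ok] = (values[ok] - lo[ok]) / span[ok, None]
    return out, ok


def build_pair_cluster_matrix(
    pairs: pd.DataFrame,
    lnc_profile: ClusterProfile,
    mrna_profile: ClusterProfile,
    rule: str = "min",
) -> PairClusterMatrix:
    """Pair x cluster activity from the two partners' min-max-scaled rows.

    ``rule="min"`` takes the elementwise minimum (default); ``"product"``
    multiplies the two scaled rows. Pairs involving a constant gene row
    (min-max undefined) are dropped and logged.
    """
    if pairs.empty:
        raise ValueError("no candidate pairs")
    if rule not in ("min", "product"):
        raise ValueError(f"unknown pair rule {rule!r}")
    lnc_scaled, lnc_ok = _minmax_rows(lnc_profile.values)
    mrna_scaled, mrna_ok = _minmax_rows(mrna_profile.values)
    l_idx = {g: i for i, g in enumerate(lnc_profile.genes)}
    m_idx = {g: i for i, g in enumerate(mrna_profile.genes)}
    li = pairs["lnc_id"].map(l_idx).to_numpy()
    mi = pairs["mrna_id"].map(m_idx).to_numpy()
    ok = lnc_ok[li] & mrna_ok[mi]
    if (~ok).any():
        logger.info("build_pair_cluster_matrix: dropped %d pairs with constant rows", int((~ok).sum()))
    li, mi = li[ok], mi[ok]
    a, b = lnc_scaled[li], mrna_scaled[mi]
    activity = np.minimum(a, b) if rule == "min" else a * b
    return PairClusterMatrix(
        pairs=pairs.loc[ok].reset_index(drop=True),
        clusters=list(lnc_profile.clusters),
        activity=activity,
    )


def assign_specific_pairs(matrix: PairClusterMatrix, cos_min: float = 0.95) -> pd.DataFrame:
    """Assign each pair to its best cluster by cosine against one-hot
    indicators; eliminate pairs whose best cosine is below ``cos_min``.

    cos(activity, e_c) = activity_c / ||activity||, so the best cluster is
    simply the argmax entry. All-zero activity rows are eliminated (logged).
    Returns the final pair table: lnc_id, mrna_id, pcc, assigned_cluster,
    cosine.
    """
    if len(matrix.clusters) < 2:
        raise ValueError("need >= 2 clusters")
    act = matrix.activity
    norms = np.linalg.norm(act, axis=1)
    nonzero = norms > 0
    if (~nonzero).any():
        logger.info("assign_specific_pairs: %d all-zero activity rows eliminated", int((~nonzero).sum()))
    best = np.zeros(len(act), dtype=np.int64)
    cosine = np.zeros(len(act))
    best[nonzero] = np.argmax(act[nonzero], axis=1)
    cosine[nonzero] = act[nonzero].max(axis=1) / norms[nonzero]
    keep = nonzero & (cosine >= cos_min)
    out = matrix.pairs.loc[keep].copy()
    out["assigned_cluster"] = [matrix.clusters[i] for i in best[keep]]
    out["cosine"] = cosine[keep]
    return out.reset_index(drop=True)


def count_pairs_by_celltype(
    pairs: pd.DataFrame, cluster_to_celltype: dict, top_k: int = 3
) -> tuple[pd.Series, pd.DataFrame]:
    """Aggregate assigned pairs by cell type.

    Unmapped clusters are counted under ``"unassigned"`` with a warning.
    Returns (counts per cell type, top-k pairs per type by cosine).
    """
    if pairs.empty:
        return pd.Series(dtype=np.int64, name="n_pairs"), pairs.copy()
    celltype = pairs["assigned_cluster"].map(cluster_to_celltype)
    if celltype.isna().any():
        logger.warning(
            "count_pairs_by_celltype: %d pairs in unmapped clusters", int(celltype.isna().sum())
        )
        celltype = celltype.fillna("unassigned")
    tab = pairs.assign(celltype=celltype)
    counts = tab["celltype"].value_counts().rename("n_pairs")
    top = (
        tab.sort_values("cosine", ascending=False)
        .groupby("celltype", group_keys=False)
        .head(top_k)
        .reset_index(drop=True)
    )
    return counts, top


def find_lnc_pairs(
    counts: CountMatrix,
    labels: pd.Series,
    annotation: pd.DataFrame,
    n_hvg: int = 2000,
    pcc_min: float = 0.85,
    cos_min: float = 0.95,
    rule: str = "min",
) -> pd.DataFrame:
    """End-to-end LncPairs: normalize, select HVGs, profile clusters, and
    run the pairing steps. Returns the final assigned pair table."""
    norm = normalize_log(counts)
    hvgs = select_hvg(norm, n=min(n_hvg, len(norm.genes)))
    profile = cluster_profile(norm, labels, genes=hvgs)
    mrna_profile, lnc_profile = split_profile(profile, annotation)
    candidates = correlate_pairs(lnc_profile, mrna_profile, pcc_min=pcc_min)
    if candidates.empty:
        return candidates.assign(assigned_cluster=pd.Series(dtype=object), cosine=pd.Series(dtype=float))
    pcm = build_pair_cluster_matrix(candidates, lnc_profile, mrna_profile, rule=rule)
    return assign_specific_pairs(pcm, cos_min=cos_min)
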
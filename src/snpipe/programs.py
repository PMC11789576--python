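"""Recurrent heterogeneous programs (RHPs) across samples via NMF sweeps.

Per sample, NMF is run on the malignant cells over a range of ranks with
deterministic SVD-based initialization; each factor becomes a candidate
program summarized by its 50 top-loading genes. Programs that recur across
ranks within a sample (sharing at least ``min_overlap`` of their top genes
with a factor at a different rank) are kept as robust, collapsed to one
representative per group. Robust programs from all samples are then
hierarchically clustered on the fraction of shared top genes; clusters
spanning enough distinct samples become RHPs with a consensus gene list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
from sklearn.decomposition import NMF

from .expression import CountMatrix, module_score

logger = logging.getLogger("snpipe")


def prepare_nmf_input(
    normalized: CountMatrix, malignant_cells: Sequence[str], min_cells: int = 50
) -> CountMatrix:
    """Center each gene over the malignant cells and clip negatives to zero.

    Centering-then-clipping keeps only above-average expression, the signal
    NMF factors over; genes left all-zero (constant genes) are dropped.
    """
    cells = [c for c in malignant_cells if c in set(normalized.barcodes)]
    if len(cells) < min_cells:
        raise ValueError(f"need >= {min_cells} malignant cells, got {len(cells)}")
    idx = {c: i for i, c in enumerate(normalized.barcodes)}
    dense = normalized.to_dense()[[idx[c] for c in cells]]
    centered = np.clip(dense - dense.mean(axis=0), 0.0, None)
    keep = np.flatnonzero(centered.sum(axis=0) > 0)
    if len(keep) < dense.shape[1]:
        logger.info("prepare_nmf_input: dropped %d all-zero genes", dense.shape[1] - len(keep))
    return CountMatrix(
        centered[:, keep], list(cells), [normalized.genes[i] for i in keep]
    )


@dataclass
class NMFProgram:
    sample_id: str
    rank_k: int
    factor_index: int
    top_genes: list[str]
    gene_scores: np.ndarray = field(repr=False)
    cell_activities: pd.Series = field(repr=False)
    converged: bool = True

    def overlap(self, other: "NMFProgram") -> int:
        return len(set(self.top_genes) & set(other.top_genes))


def run_nmf_sweep(
    prepared: CountMatrix,
    sample_id: str,
    ranks: Sequence[int] = range(4, 10),
    top_n: int = 50,
    seed: int = 0,
    max_iter: int = 500,
) -> list[NMFProgram]:
    """Factorize at every rank; each factor yields one candidate program.

    Initialization is NNDSVD (deterministic given the data), so the sweep
    is reproducible; non-converged fits are kept but flagged.
    """
    X = prepared.to_dense()
    if max(ranks) >= min(X.shape):
        raise ValueError("max rank must be below both matrix dimensions")
    programs: list[NMFProgram] = []
    for k in ranks:
        model = NMF(
            n_components=k,
            init="nndsvd",
            max_iter=max_iter,
            random_state=seed,
            tol=1e-4,
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence flagged below instead
            W = model.fit_transform(X)
        converged = model.n_iter_ < max_iter
        H = model.components_
        for f in range(k):
            order = np.argsort(-H[f])
            top = order[: min(top_n, H.shape[1])]
            if len(top) < top_n:
                logger.warning("factor has only %d genes for a top-%d list", len(top), top_n)
            programs.append(
                NMFProgram(
                    sample_id=sample_id,
                    rank_k=k,
                    factor_index=f,
                    top_genes=[prepared.genes[i] for i in top],
                    gene_scores=H[f, top],
                    cell_activities=pd.Series(W[:, f], index=prepared.barcodes),
                    converged=converged,
                )
            )
    return programs


def robust_programs(programs: list[NMFProgram], min_overlap: int = 35) -> list[NMFProgram]:
    """Keep programs that recur across ranks within their sample.

    A program is robust iff some program at a *different* rank of the same
    sample shares >= ``min_overlap`` top genes. Recurring programs are then
    deduplicated greedily: the program with the strongest recurrence (the
    highest mean overlap to its direct partners) is kept as a
    representative and its partners are removed, repeating until no
    recurring programs remain. Greedy neighbourhood selection — rather than
    collapsing whole connected components — keeps distinct programs that a
    chain of mixed low-rank factors would otherwise fuse.
    """
    ranks = {p.rank_k for p in programs}
    if len(ranks) < 2:
        raise ValueError("need a sweep over >= 2 ranks to assess robustness")
    out: list[NMFProgram] = []
    for sample_id in sorted({p.sample_id for p in programs}):
        ps = [p for p in programs if p.sample_id == sample_id]
        n = len(ps)
        adj: list[set[int]] = [set() for _ in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                if ps[i].rank_k != ps[j].rank_k and ps[i].overlap(ps[j]) >= min_overlap:
                    adj[i].add(j)
                    adj[j].add(i)
        alive = {i for i in range(n) if adj[i]}
        while alive:
            def _strength(i: int) -> tuple:
                partners = adj[i] & alive
                mean_ov = np.mean([ps[i].overlap(ps[j]) for j in partners]) if partners else 0.0
                return (-mean_ov, -len(partners), ps[i].rank_k, ps[i].factor_index)

            best = min((i for i in alive), key=_strength)
            if not (adj[best] & alive):
                alive.discard(best)
                continue
            out.append(ps[best])
            alive -= adj[best] | {best}
    return out


@dataclass
class RHP:
    members: list[NMFProgram]
    consensus_genes: list[str]
    label: str = ""

    @property
    def samples(self) -> set[str]:
        return {p.sample_id for p in self.members}


def program_similarity(programs: list[NMFProgram], top_n: int = 50) -> np.ndarray:
    """Pairwise shared-top-gene fraction, |top_i & top_j| / top_n."""
    n = len(programs)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = programs[i].overlap(programs[j]) / top_n
    return sim


def cluster_programs(
    programs: list[NMFProgram],
    min_samples: int = 2,
    cut_height: float = 0.8,
    consensus_fraction: float = 0.5,
    top_n: int = 50,
) -> list[RHP]:
    """Group robust programs across samples into RHPs.

    Average-linkage hierarchical clustering on (1 - shared-gene fraction),
    cut at ``cut_height``; clusters spanning >= ``min_samples`` distinct
    samples become RHPs. The RHP signature is its top ``top_n`` genes
    ranked by how many member programs carry them (ties alphabetical),
    keeping only genes present in at least ``consensus_fraction`` of the
    members that could be beaten by recurrent genes — mixture members that
    join a cluster therefore cannot dilute a signature carried by the
    cleanly recurring core.
    """
    samples = {p.sample_id for p in programs}
    if len(samples) < 2:
        logger.warning("cluster_programs: only one sample contributed; no RHPs")
        return []
    sim = program_similarity(programs, top_n=top_n)
    if len(programs) == 1:
        return []
    dist = scipy.spatial.distance.squareform(1.0 - sim, checks=False)
    linkage = scipy.cluster.hierarchy.linkage(dist, method="average")
    assignment = scipy.cluster.hierarchy.fcluster(linkage, t=cut_height, criterion="distance")
    rhps: list[RHP] = []
    for cl in np.unique(assignment):
        members = [programs[i] for i in np.flatnonzero(assignment == cl)]
        covered = {p.sample_id for p in members}
        if len(covered) < min_samples:
            continue
        gene_counts = pd.Series([g for p in members for g in p.top_genes]).value_counts()
        ordered = sorted(gene_counts.index, key=lambda g: (-gene_counts[g], g))
        min_count = max(2, int(np.ceil(consensus_fraction * len({p.sample_id for p in members}))))
        consensus = [g for g in ordered if gene_counts[g] >= min_count][:top_n]
        rhps.append(
            RHP(members=members, consensus_genes=consensus, label=f"RHP{len(rhps) + 1}")
        )
    return rhps


def score_cells_by_rhp(
    normalized: CountMatrix, rhp: RHP, n_bins: int = 25, n_ctrl: int = 100, seed: int = 0
) -> pd.Series:
    """Per-cell activity of an RHP: module score of its consensus genes."""
    return module_score(
        normalized, rhp.consensus_genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed
    ).rename(rhp.label or "rhp_score")
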
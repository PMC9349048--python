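"""Pseudo-cell aggregation and neighbor-voting AUROC cluster mapping.

Pseudo-cells are disjoint groups of ``group_size`` cells drawn without
replacement within each cluster; their UMI counts are summed by gene and
rescaled to CP10K, then z-transformed per gene across all pseudo-cells
of a dataset. Each target pseudo-cell's vote for a source cluster is its
mean Pearson correlation with that cluster's pseudo-cells (self
correlations excluded within a dataset); the AUROC of a cluster pair is
the midrank Mann–Whitney probability that a member pseudo-cell's vote
exceeds a non-member's, averaged over both voting directions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import hier
from .core import UmiMatrix
from .orthology import OrthoMap

__all__ = [
    "PseudoCellMatrix",
    "AurocMatrix",
    "make_pseudocells",
    "standardize",
    "auroc_from_votes",
    "auroc_pair",
    "mean_auroc_matrix",
    "auroc_dendrogram",
    "correspondence_network",
    "marker_ortho_genes",
]


@dataclass
class PseudoCellMatrix:
    """Pseudo-cells × genes with provenance of each aggregate.

    ``stage`` tracks the processing state: ``raw-sum`` (summed UMIs),
    ``cp10k`` (library-size normalized) or ``z`` (gene-standardized).
    """

    values: np.ndarray
    genes: pd.Index
    clusters: np.ndarray
    members: list[list[str]]
    dataset: str = "data"
    stage: str = "raw-sum"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.clusters = np.asarray(self.clusters, dtype=object)
        if self.values.shape != (len(self.clusters), len(self.genes)):
            raise ValueError("values shape must be pseudo-cells x genes")
        used = [c for group in self.members for c in group]
        if len(used) != len(set(used)):
            raise ValueError("a cell may belong to at most one pseudo-cell")

    @property
    def n_pseudocells(self) -> int:
        return self.values.shape[0]

    def cluster_names(self) -> list[str]:
        return sorted(set(self.clusters))


def make_pseudocells(
    matrix: UmiMatrix,
    group_size: int = 10,
    seed: int = 0,
    labels: Optional[pd.Series] = None,
    dataset: str = "data",
    normalize: bool = True,
) -> PseudoCellMatrix:
    """Partition each cluster into disjoint groups and sum their UMIs.

    Cells are shuffled per cluster with ``seed``; the remainder of each
    cluster (fewer than ``group_size`` cells) is dropped and counted in
    ``n_dropped``. With ``normalize`` the summed profiles are rescaled to
    CP10K (the default); otherwise the raw sums are returned.
    """
    if group_size < 2:
        raise ValueError("group_size must be at least 2")
    if labels is None:
        labels = matrix.obs["cluster"]
    labels = pd.Series(np.asarray(labels), index=matrix.cells)
    rng = np.random.default_rng(seed)
    rows, row_clusters, members = [], [], []
    n_dropped = 0
    for cluster in sorted(labels.unique()):
        idx = np.flatnonzero((labels == cluster).to_numpy())
        perm = rng.permutation(idx)
        n_groups = len(perm) // group_size
        n_dropped += len(perm) - n_groups * group_size
        if n_groups == 0:
            warnings.warn(
                f"cluster {cluster!r} has fewer than {group_size} cells; "
                "no pseudo-cells formed"
            )
            continue
        for g in range(n_groups):
            take = perm[g * group_size : (g + 1) * group_size]
            rows.append(np.asarray(matrix.counts[take].sum(axis=0)).ravel())
            row_clusters.append(cluster)
            members.append(list(matrix.cells[take]))
    if not rows:
        raise ValueError("no cluster yielded any pseudo-cell")
    values = np.vstack(rows).astype(float)
    stage = "raw-sum"
    if normalize:
        totals = values.sum(axis=1, keepdims=True)
        values = values / totals * 1e4
        stage = "cp10k"
    return PseudoCellMatrix(
        values, matrix.genes, np.array(row_clusters, dtype=object), members,
        dataset=dataset, stage=stage, n_dropped=n_dropped,
    )


def standardize(pcm: PseudoCellMatrix, gene_subset: Sequence[str]) -> PseudoCellMatrix:
    """z = (x − m) / s.d. per gene across the dataset's pseudo-cells.

    Restricted to ``gene_subset``; population standard deviation; genes
    with zero variance get z = 0 everywhere.
    """
    genes = pd.Index(gene_subset)
    if len(genes) == 0:
        raise ValueError("empty gene subset")
    if pcm.n_pseudocells < 2:
        raise ValueError("at least two pseudo-cells required")
    idx = pcm.genes.get_indexer(genes)
    if (idx < 0).any():
        missing = genes[idx < 0]
        raise KeyError(f"genes absent from pseudo-cell matrix: {list(missing[:5])}")
    x = pcm.values[:, idx]
    mean = x.mean(axis=0)
    sd = x.std(axis=0)  # population s.d.
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (x - mean) / sd, 0.0)
    return PseudoCellMatrix(
        z, genes, pcm.clusters, pcm.members,
        dataset=pcm.dataset, stage="z", n_dropped=pcm.n_dropped,
    )


# ---------------------------------------------------------------------------
# AUROC machinery
# ---------------------------------------------------------------------------


def _row_standardize(x: np.ndarray) -> np.ndarray:
    """Center and scale rows so that x @ x.T / n_genes gives Pearson r."""
    xc = x - x.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(xc, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norm > 0, xc / norm, 0.0)
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return _row_standardize(a) @ _row_standardize(b).T


def auroc_from_votes(votes: np.ndarray, is_member: np.ndarray) -> float:
    """Midrank Mann–Whitney AUROC of member votes vs non-member votes."""
    votes = np.asarray(votes, dtype=float)
    is_member = np.asarray(is_member, dtype=bool)
    n_pos = int(is_member.sum())
    n_neg = votes.size - n_pos
    if n_pos == 0:
        raise ValueError("target cluster has no pseudo-cells")
    if n_neg == 0:
        raise ValueError("AUROC undefined: no non-member pseudo-cells in target")
    ranks = stats.rankdata(votes)
    r_pos = ranks[is_member].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _cluster_votes(
    corr: np.ndarray,
    source_members: np.ndarray,
    exclude_self: bool,
) -> np.ndarray:
    """Mean correlation of every target pseudo-cell with the source cluster.

    ``corr`` is source-pseudocells × target-pseudocells. With
    ``exclude_self`` (within-dataset use, square ``corr``), the diagonal
    term is removed from a member's own vote; a singleton source cluster
    yields NaN for its own pseudo-cell.
    """
    sums = corr[source_members].sum(axis=0)
    counts = np.full(corr.shape[1], float(source_members.sum()))
    if exclude_self:
        if corr.shape[0] != corr.shape[1]:
            raise ValueError("self-exclusion requires a square correlation matrix")
        diag = np.diag(corr)
        sums = sums - np.where(source_members, diag, 0.0)
        counts = counts - source_members.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / counts, np.nan)


def auroc_pair(
    source_pcm: PseudoCellMatrix,
    target_pcm: PseudoCellMatrix,
    source_cluster: str,
    target_cluster: str,
) -> float:
    """One-directional neighbor-voting AUROC for a cluster pair.

    Votes of target pseudo-cells are their mean Pearson correlation with
    the source cluster's pseudo-cells; when source and target are the
    same object, self-correlations are excluded from members' votes.
    """
    if not source_pcm.genes.equals(target_pcm.genes):
        raise ValueError("pseudo-cell matrices must share the gene subset")
    src_mask = source_pcm.clusters == source_cluster
    if not src_mask.any():
        raise ValueError(f"source cluster {source_cluster!r} has no pseudo-cells")
    same = source_pcm is target_pcm
    corr = _pearson(source_pcm.values, target_pcm.values)
    votes = _cluster_votes(corr, src_mask, exclude_self=same)
    valid = ~np.isnan(votes)
    return auroc_from_votes(
        votes[valid], (target_pcm.clusters == target_cluster)[valid]
    )


@dataclass
class AurocMatrix:
    """Symmetric cluster × cluster mean-AUROC grid, diagonal fixed at 1.

    Row/column labels are ``dataset:cluster``.
    """

    values: pd.DataFrame
    dataset_of: dict[str, str]

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if self.values.shape[0] != self.values.shape[1]:
            raise ValueError("AUROC matrix must be square")
        if ((v < 0) | (v > 1)).any():
            raise ValueError("AUROC entries must lie in [0, 1]")

    def between_block(self, source_dataset: str, target_dataset: str) -> pd.DataFrame:
        """Between-dataset block with bare cluster names on both axes."""
        rows = [l for l in self.values.index if self.dataset_of[l] == source_dataset]
        cols = [l for l in self.values.index if self.dataset_of[l] == target_dataset]
        if not rows or not cols:
            raise KeyError("unknown dataset name")
        block = self.values.loc[rows, cols].copy()
        block.index = [l.split(":", 1)[1] for l in rows]
        block.columns = [l.split(":", 1)[1] for l in cols]
        return block

    def write(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="cluster")

    @classmethod
    def read(cls, path: str | Path) -> "AurocMatrix":
        df = pd.read_csv(path, sep="\t", index_col="cluster")
        dataset_of = {l: l.split(":", 1)[0] for l in df.index}
        return cls(df, dataset_of)


def mean_auroc_matrix(pcm_a: PseudoCellMatrix, pcm_b: PseudoCellMatrix) -> AurocMatrix:
    """Mean AUROC over both voting directions for every cluster pair.

    Covers within- and between-dataset pairs; within-dataset votes
    exclude self-correlations; the diagonal is defined as 1.
    """
    if not pcm_a.genes.equals(pcm_b.genes):
        raise ValueError("pseudo-cell matrices must share the gene subset")
    if pcm_a.dataset == pcm_b.dataset:
        raise ValueError("datasets must carry distinct names")

    labels = [f"{pcm_a.dataset}:{c}" for c in pcm_a.cluster_names()] + [
        f"{pcm_b.dataset}:{c}" for c in pcm_b.cluster_names()
    ]
    out = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)

    def one_direction(src: PseudoCellMatrix, tgt: PseudoCellMatrix) -> pd.DataFrame:
        same = src is tgt
        corr = _pearson(src.values, tgt.values)
        scores = {}
        for sc in src.cluster_names():
            votes = _cluster_votes(corr, src.clusters == sc, exclude_self=same)
            valid = ~np.isnan(votes)
            row = {}
            for tc in tgt.cluster_names():
                if same and tc == sc:
                    continue  # diagonal is defined as 1, never computed
                row[tc] = auroc_from_votes(
                    votes[valid], (tgt.clusters == tc)[valid]
                )
            scores[sc] = row
        return pd.DataFrame(scores).T  # source rows x target cols

    ab = one_direction(pcm_a, pcm_b)
    ba = one_direction(pcm_b, pcm_a)
    aa = one_direction(pcm_a, pcm_a)
    bb = one_direction(pcm_b, pcm_b)

    def fill(block: pd.DataFrame, rev: pd.DataFrame, src_ds: str, tgt_ds: str) -> None:
        for sc in block.index:
            for tc in block.columns:
                if src_ds == tgt_ds and sc == tc:
                    continue
                score = (block.loc[sc, tc] + rev.loc[tc, sc]) / 2.0
                out.loc[f"{src_ds}:{sc}", f"{tgt_ds}:{tc}"] = score
                out.loc[f"{tgt_ds}:{tc}", f"{src_ds}:{sc}"] = score

    fill(ab, ba, pcm_a.dataset, pcm_b.dataset)
    fill(aa, aa, pcm_a.dataset, pcm_a.dataset)
    fill(bb, bb, pcm_b.dataset, pcm_b.dataset)
    dataset_of = {l: l.split(":", 1)[0] for l in labels}
    return AurocMatrix(out, dataset_of)


def auroc_dendrogram(auroc: AurocMatrix) -> hier.Node:
    """Ward tree of all clusters with distance 1 − AUROC (clamped ≥ 0)."""
    dist = np.clip(1.0 - auroc.values.to_numpy(dtype=float), 0.0, None)
    np.fill_diagonal(dist, 0.0)
    return hier.ward_tree(dist, list(auroc.values.index))


def correspondence_network(
    auroc: AurocMatrix,
    source_dataset: str,
    target_dataset: str,
    min_auroc: float = 0.80,
    second_hit_gap: float = 0.05,
) -> pd.DataFrame:
    """Top-hit edges per source cluster, plus near-tied second hits.

    An edge requires AUROC strictly above ``min_auroc``; a second edge is
    added only when it also clears the threshold and trails the top hit
    by strictly less than ``second_hit_gap``.
    """
    block = auroc.between_block(source_dataset, target_dataset)
    edges = []
    for sc, row in block.iterrows():
        ordered = row.sort_values(ascending=False, kind="mergesort")
        ordered = ordered.loc[sorted(ordered.index)].sort_values(
            ascending=False, kind="mergesort"
        )  # deterministic tie order by label
        top_label, top = ordered.index[0], float(ordered.iloc[0])
        if top > min_auroc:
            edges.append((sc, top_label, top, "top"))
            if len(ordered) > 1:
                second_label, second = ordered.index[1], float(ordered.iloc[1])
                if second > min_auroc and (top - second) < second_hit_gap:
                    edges.append((sc, second_label, second, "second"))
    return pd.DataFrame(edges, columns=["source", "target", "auroc", "rank"])


def marker_ortho_genes(
    ortho: OrthoMap,
    markers_a: Sequence[str],
    markers_b: Sequence[str],
) -> tuple[list[str], list[str]]:
    """Aligned gene lists: orthologous pairs that are markers in ≥ 1 dataset.

    Returns two equally long lists (genes of dataset A, genes of dataset
    B) in matching pair order, restricted to pairs where either side is a
    cluster marker.
    """
    set_a, set_b = set(markers_a), set(markers_b)
    genes_a, genes_b = [], []
    for ga, gb in sorted(ortho.pairs):
        if ga in set_a or gb in set_b:
            genes_a.append(ga)
            genes_b.append(gb)
    return genes_a, genes_b
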
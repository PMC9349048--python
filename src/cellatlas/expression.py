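"""Cluster expression summaries, marker/DEG calling and dendrograms.

Marker detection mirrors the one-vs-rest Wilcoxon rank-sum workflow
(min.pct / log-fold-change prefilters, positive-only by default) on
log-transformed CP10K. DEG significance uses the gate triple
FDR < 0.05, fold change > 1.25 and > 20% expressing cells in the
up-regulated group. Fold-change thresholds are natural-log.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import hier
from .core import ClusterExpression, UmiMatrix, bh_fdr
from .preprocess import cp10k

__all__ = [
    "cluster_expression",
    "find_markers",
    "find_degs",
    "correlation_dendrogram",
]

_EPS = 1e-9


def cluster_expression(
    matrix: UmiMatrix, labels: Optional[pd.Series] = None
) -> ClusterExpression:
    """Mean within-cell UMI fraction per gene, × 1e6, per cluster.

    For each cluster the value of gene g is the mean over member cells of
    (UMIs of g in the cell / total UMIs of the cell) × 1e6.
    """
    labels = _resolve_labels(matrix, labels)
    totals = matrix.cell_totals()
    if (totals == 0).any():
        raise ValueError("cells with zero total UMIs; run QC first")
    fractions = matrix.counts.multiply(1e6 / totals[:, None]).tocsr()
    groups = pd.Series(labels.values, index=np.arange(matrix.n_cells)).groupby(
        labels.values
    )
    rows, n_cells = {}, {}
    for cluster, idx in groups.groups.items():
        idx = np.asarray(idx)
        if idx.size == 0:
            raise ValueError(f"empty cluster {cluster!r}")
        rows[cluster] = np.asarray(fractions[idx].mean(axis=0)).ravel()
        n_cells[cluster] = idx.size
    values = pd.DataFrame.from_dict(rows, orient="index", columns=matrix.genes)
    values = values.sort_index()
    return ClusterExpression(values, pd.Series(n_cells).sort_index())


def _resolve_labels(matrix: UmiMatrix, labels: Optional[pd.Series]) -> pd.Series:
    if labels is None:
        if "cluster" not in matrix.obs:
            raise ValueError("no labels given and no 'cluster' column in obs")
        labels = matrix.obs["cluster"]
    labels = pd.Series(labels)
    if len(labels) != matrix.n_cells:
        raise ValueError("one label per cell required")
    if labels.isna().any():
        raise ValueError("every cell must be labelled")
    return labels.reset_index(drop=True)


def rank_sum_pvalues(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p per column (tie-corrected normal
    approximation with continuity correction, as in R's ``wilcox.test``)."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n = values.shape[0]
    n1 = int(mask.sum())
    n2 = n - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(values, axis=0)
    r1 = ranks[mask].sum(axis=0)
    mu = n1 * (n + 1) / 2.0
    tie_term = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        _, counts = np.unique(values[:, j], return_counts=True)
        tie_term[j] = float((counts.astype(float) ** 3 - counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    z = np.zeros_like(r1)
    ok = var > 0
    z[ok] = (np.abs(r1[ok] - mu) - 0.5).clip(min=0.0) / np.sqrt(var[ok])
    p = np.ones_like(r1)
    p[ok] = np.minimum(2.0 * stats.norm.sf(z[ok]), 1.0)
    return p


def find_markers(
    matrix: UmiMatrix,
    labels: Optional[pd.Series] = None,
    min_pct: float = 0.25,
    min_logfc: float = 0.25,
    positive_only: bool = True,
    fdr_level: float = 0.05,
    min_cluster_size: int = 3,
) -> pd.DataFrame:
    """One-vs-rest rank-sum marker detection per cluster.

    Genes enter the test only if expressed (UMI ≥ 1) in at least
    ``min_pct`` of the cluster's cells and with natural-log fold change of
    mean CP10K at least ``min_logfc`` (up-regulated only when
    ``positive_only``). BH adjustment runs across the tested genes of each
    cluster. Clusters with fewer than ``min_cluster_size`` cells are
    skipped with a warning.
    """
    labels = _resolve_labels(matrix, labels)
    if labels.nunique() < 2:
        raise ValueError("at least two clusters required")
    norm = cp10k(matrix)
    dense = np.asarray(norm.todense())
    logdata = np.log1p(dense)
    expressed = np.asarray((matrix.counts > 0).todense())

    frames = []
    for cluster in sorted(labels.unique()):
        mask = (labels == cluster).to_numpy()
        if mask.sum() < min_cluster_size:
            warnings.warn(
                f"cluster {cluster!r} has fewer than {min_cluster_size} cells; skipped"
            )
            continue
        pct_in = expressed[mask].mean(axis=0)
        pct_out = expressed[~mask].mean(axis=0)
        mean_in = dense[mask].mean(axis=0)
        mean_out = dense[~mask].mean(axis=0)
        log_fc = np.log((mean_in + _EPS) / (mean_out + _EPS))
        cand = pct_in >= min_pct
        cand &= log_fc >= min_logfc if positive_only else np.abs(log_fc) >= min_logfc
        if not cand.any():
            continue
        p = rank_sum_pvalues(logdata[:, cand], mask)
        sub = pd.DataFrame(
            {
                "gene": matrix.genes[cand],
                "cluster": cluster,
                "log_fc": log_fc[cand],
                "fold_change": np.exp(log_fc[cand]),
                "pct_in": pct_in[cand],
                "pct_out": pct_out[cand],
                "p_value": p,
            }
        )
        sub["fdr"] = bh_fdr(sub["p_value"].to_numpy())
        frames.append(sub)
    if not frames:
        return pd.DataFrame(
            columns=[
                "gene", "cluster", "log_fc", "fold_change", "pct_in",
                "pct_out", "p_value", "fdr", "significant",
            ]
        )
    out = pd.concat(frames, ignore_index=True)
    out["significant"] = out["fdr"] < fdr_level
    return out


def find_degs(
    matrix: UmiMatrix,
    cells_a: Sequence,
    cells_b: Sequence,
    fdr_level: float = 0.05,
    min_fold: float = 1.25,
    min_pct: float = 0.20,
) -> pd.DataFrame:
    """Two-sided rank-sum DEG test between two cell groups.

    Fold change is the ratio of mean CP10K (pseudo-count 1e-9) oriented so
    that it is ≥ 1 for the up-regulated group; ``significant`` requires
    FDR < ``fdr_level``, fold > ``min_fold`` and > ``min_pct`` of the
    up-group's cells expressing the gene.
    """
    mask_a = _as_mask(matrix, cells_a)
    mask_b = _as_mask(matrix, cells_b)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both groups must be non-empty")
    if (mask_a & mask_b).any():
        raise ValueError("groups overlap")
    if (mask_a == mask_b).all():
        raise ValueError("groups are identical")
    sub = matrix.subset_cells(mask_a | mask_b)
    in_a = mask_a[mask_a | mask_b]
    dense = np.asarray(cp10k(sub).todense())
    expressed = np.asarray((sub.counts > 0).todense())
    p = rank_sum_pvalues(np.log1p(dense), in_a)
    mean_a = dense[in_a].mean(axis=0)
    mean_b = dense[~in_a].mean(axis=0)
    ratio = (mean_a + _EPS) / (mean_b + _EPS)
    up_is_a = ratio >= 1.0
    fold = np.where(up_is_a, ratio, 1.0 / ratio)
    pct_up = np.where(
        up_is_a, expressed[in_a].mean(axis=0), expressed[~in_a].mean(axis=0)
    )
    out = pd.DataFrame(
        {
            "gene": sub.genes,
            "up_group": np.where(up_is_a, "a", "b"),
            "fold_change": fold,
            "pct_expressing": pct_up,
            "p_value": p,
        }
    )
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    out["significant"] = (
        (out["fdr"] < fdr_level)
        & (out["fold_change"] > min_fold)
        & (out["pct_expressing"] > min_pct)
    )
    return out


def _as_mask(matrix: UmiMatrix, cells) -> np.ndarray:
    arr = np.asarray(cells)
    if arr.dtype == bool:
        if arr.size != matrix.n_cells:
            raise ValueError("boolean mask length must equal cell count")
        return arr
    idx = matrix.obs.index.get_indexer(pd.Index(cells))
    if (idx < 0).any():
        raise KeyError("unknown cell ids in group")
    mask = np.zeros(matrix.n_cells, dtype=bool)
    mask[idx] = True
    return mask


def correlation_dendrogram(
    expr: ClusterExpression,
    top_n_genes: int = 8000,
    bootstrap_reps: int = 0,
    seed: int = 0,
) -> hier.Node:
    """Ward dendrogram of cluster profiles on 1 − Pearson distance.

    Profiles are restricted to the ``top_n_genes`` most highly expressed
    genes (mean across the clusters at hand; ties broken by gene id).
    Branch support, when ``bootstrap_reps`` > 0, is the fraction of
    gene-bootstrap trees reproducing each clade.
    """
    if len(expr.clusters) < 2:
        raise ValueError("at least two clusters required")
    means = expr.values.mean(axis=0)
    if top_n_genes > len(means):
        warnings.warn(
            f"top_n_genes={top_n_genes} exceeds gene count {len(means)}; using all"
        )
        top_n_genes = len(means)
    ranking = sorted(means.index, key=lambda g: (-means[g], g))
    profiles = expr.values[ranking[:top_n_genes]]
    rng = np.random.default_rng(seed)
    return hier.bootstrap_support(profiles, bootstrap_reps, rng)
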
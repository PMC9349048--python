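"""Shared data containers and plain-text I/O.

The package moves three tabular objects between stages:

* :class:`UmiMatrix` — sparse cells × genes UMI counts plus per-cell
  metadata (sample, phenotype, cluster, species).
* :class:`ClusterExpression` — dense clusters × genes summary profiles.
* :class:`CompositionTable` — samples × clusters cell counts with a
  per-sample phenotype design.

All on-disk formats are plain text: Matrix Market for counts, TSV for
metadata and summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = ["UmiMatrix", "ClusterExpression", "CompositionTable"]


@dataclass
class UmiMatrix:
    """Sparse UMI count matrix (cells × genes) with per-cell metadata.

    Parameters
    ----------
    counts
        Non-negative integer counts, one row per cell.
    genes
        Gene identifiers, one per column.
    obs
        Per-cell metadata indexed by cell id. Conventional columns are
        ``sample`` (replicate id), ``phenotype``, ``cluster`` and
        ``species``; none is mandatory at construction time.
    """

    counts: sp.csr_matrix
    genes: pd.Index
    obs: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.genes = pd.Index(self.genes)
        if self.counts.shape != (len(self.obs), len(self.genes)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.obs)} cells x {len(self.genes)} genes"
            )
        if self.genes.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        if self.obs.index.has_duplicates:
            raise ValueError("duplicate cell identifiers")

    # -- basic accessors -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cells(self) -> pd.Index:
        return self.obs.index

    def cell_totals(self) -> np.ndarray:
        """Total UMIs per cell."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Number of genes with at least one UMI, per cell."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    # -- subsetting ------------------------------------------------------
    def subset_cells(self, selector) -> "UmiMatrix":
        """Subset by boolean mask (cell order kept) or list of cell ids."""
        if isinstance(selector, (pd.Series, np.ndarray, list)) and (
            np.asarray(selector).dtype == bool
        ):
            mask = np.asarray(selector)
            idx = np.flatnonzero(mask)
        else:
            idx = self.obs.index.get_indexer(pd.Index(selector))
            if (idx < 0).any():
                missing = pd.Index(selector)[idx < 0]
                raise KeyError(f"unknown cell ids: {list(missing[:5])}")
        return UmiMatrix(self.counts[idx], self.genes, self.obs.iloc[idx].copy())

    def subset_genes(self, genes: Sequence[str]) -> "UmiMatrix":
        idx = self.genes.get_indexer(pd.Index(genes))
        if (idx < 0).any():
            missing = pd.Index(genes)[idx < 0]
            raise KeyError(f"unknown genes: {list(missing[:5])}")
        return UmiMatrix(self.counts[:, idx], pd.Index(genes), self.obs.copy())

    # -- I/O -------------------------------------------------------------
    def write(self, directory: str | Path) -> None:
        """Write ``matrix.mtx`` (genes × cells), ``genes.tsv``, ``cells.tsv``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        mmwrite(str(directory / "matrix.mtx"), self.counts.T.tocoo(), field="integer")
        pd.DataFrame({"gene": self.genes}).to_csv(
            directory / "genes.tsv", sep="\t", index=False
        )
        cells = self.obs.copy()
        cells.insert(0, "cell", cells.index)
        cells.to_csv(directory / "cells.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, directory: str | Path) -> "UmiMatrix":
        directory = Path(directory)
        counts = sp.csr_matrix(mmread(str(directory / "matrix.mtx")).T)
        genes = pd.read_csv(directory / "genes.tsv", sep="\t")["gene"]
        cells = pd.read_csv(directory / "cells.tsv", sep="\t").set_index("cell")
        return cls(counts, pd.Index(genes), cells)


@dataclass
class ClusterExpression:
    """Per-cluster expression summaries on a per-million-of-fraction scale.

    ``values`` is clusters × genes; entry (c, g) is the mean over member
    cells of (gene UMIs / cell total UMIs) × 1e6. ``n_cells`` records the
    member count behind each row.
    """

    values: pd.DataFrame
    n_cells: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.n_cells.index):
            raise ValueError("values and n_cells must share the cluster index")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def clusters(self) -> pd.Index:
        return self.values.index

    def mean_cp10k(self) -> pd.Series:
        """Mean expression per gene across clusters, rescaled to CP10K."""
        return self.values.mean(axis=0) / 100.0

    def write(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "n_cells", self.n_cells)
        out.to_csv(path, sep="\t", index_label="cluster")

    @classmethod
    def read(cls, path: str | Path) -> "ClusterExpression":
        df = pd.read_csv(path, sep="\t", index_col="cluster")
        n_cells = df.pop("n_cells")
        return cls(df, n_cells)


@dataclass
class CompositionTable:
    """Samples × clusters cell counts plus per-sample phenotype labels."""

    counts: pd.DataFrame
    phenotype: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("cell counts must be non-negative")
        if not self.counts.index.equals(pd.Index(self.phenotype.index)):
            raise ValueError("counts and phenotype must share the sample index")
        if (self.counts.sum(axis=1) == 0).any():
            empty = self.counts.index[self.counts.sum(axis=1) == 0]
            raise ValueError(f"samples with zero cells: {list(empty)}")

    @property
    def samples(self) -> pd.Index:
        return self.counts.index

    @property
    def clusters(self) -> pd.Index:
        return self.counts.columns

    @classmethod
    def from_umi(
        cls,
        matrix: UmiMatrix,
        sample_col: str = "sample",
        phenotype_col: str = "phenotype",
        cluster_col: str = "cluster",
    ) -> "CompositionTable":
        obs = matrix.obs
        counts = (
            pd.crosstab(obs[sample_col], obs[cluster_col])
            .rename_axis(index="sample", columns="cluster")
        )
        pheno = obs.groupby(sample_col)[phenotype_col].agg(
            lambda s: s.iloc[0]
        ).reindex(counts.index)
        return cls(counts, pheno)

    def write(self, counts_path: str | Path, samples_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="sample")
        pd.DataFrame(
            {"sample": self.phenotype.index, "phenotype": self.phenotype.values}
        ).to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def read(cls, counts_path: str | Path, samples_path: str | Path) -> "CompositionTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col="sample")
        sheet = pd.read_csv(samples_path, sep="\t").set_index("sample")
        return cls(counts, sheet["phenotype"].reindex(counts.index))


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out
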
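"""Alignment-record filtering, nucleus QC and normalization.

The read filter drops three classes of alignments: multi-mapped records
(reported multiplicity > 1), spliced records spanning any gap longer
than 50 kb, and spliced records whose intron terminal dinucleotides are
not canonical (GT/AG, GC/AG or AT/AC) on either genomic orientation.
Nucleus QC keeps cells with 200–2,000 detected genes (inclusive) and a
mitochondrial UMI fraction of at most 1%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import scipy.sparse as sp
from Bio import SeqIO

from .core import UmiMatrix

__all__ = [
    "AlignmentRecord",
    "FilterResult",
    "CellQcReport",
    "read_sam",
    "read_genome",
    "filter_alignments",
    "qc_nuclei",
    "cp10k",
    "pseudobulk_correlation",
]

MAX_INTRON_GAP = 50_000
CANONICAL_MOTIFS = {("GT", "AG"), ("GC", "AG"), ("AT", "AC")}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class AlignmentRecord:
    """One alignment: sorted, non-overlapping reference blocks + multiplicity."""

    read_id: str
    chrom: str
    blocks: list[tuple[int, int]]  # half-open genomic intervals
    n_hits: int = 1

    def __post_init__(self) -> None:
        for (s0, e0), (s1, e1) in zip(self.blocks, self.blocks[1:]):
            if s1 < e0:
                raise ValueError(f"{self.read_id}: blocks overlap or are unsorted")
        for s, e in self.blocks:
            if e <= s:
                raise ValueError(f"{self.read_id}: empty alignment block")

    def gaps(self) -> list[tuple[int, int]]:
        """Half-open intron gaps between consecutive blocks."""
        return [
            (e0, s1) for (s0, e0), (s1, e1) in zip(self.blocks, self.blocks[1:])
        ]


def _blocks_from_cigar(pos: int, cigartuples) -> list[tuple[int, int]]:
    """Reference blocks with N as the only block separator (D extends)."""
    blocks: list[tuple[int, int]] = []
    start = pos
    cur = pos
    for op, length in cigartuples:
        if op in (0, 7, 8, 2):  # M, =, X, D consume reference within a block
            cur += length
        elif op == 3:  # N closes the block
            blocks.append((start, cur))
            cur += length
            start = cur
        # I, S, H, P do not consume reference
    blocks.append((start, cur))
    return blocks


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Load primary alignment records from a SAM/BAM file."""
    records = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            n_hits = aln.get_tag("NH") if aln.has_tag("NH") else 1
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    chrom=aln.reference_name,
                    blocks=_blocks_from_cigar(aln.reference_start, aln.cigartuples),
                    n_hits=int(n_hits),
                )
            )
    return records


def read_genome(path: str | Path) -> dict[str, str]:
    """FASTA → {chrom: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


@dataclass
class FilterResult:
    passed: set[str]
    discarded: dict[str, int] = field(
        default_factory=lambda: {"multimapped": 0, "long_gap": 0, "noncanonical": 0}
    )


def _splice_motif_ok(seq: str, gap_start: int, gap_end: int) -> bool:
    donor = seq[gap_start : gap_start + 2]
    acceptor = seq[gap_end - 2 : gap_end]
    if (donor, acceptor) in CANONICAL_MOTIFS:
        return True
    # the same junction read on the opposite genomic strand
    rd = acceptor.translate(_COMPLEMENT)[::-1]
    ra = donor.translate(_COMPLEMENT)[::-1]
    return (rd, ra) in CANONICAL_MOTIFS


def filter_alignments(
    records: Iterable[AlignmentRecord], genome: Mapping[str, str]
) -> FilterResult:
    """Apply the three discard rules; each record is counted at most once.

    Raises ``ValueError`` if a spliced record names an absent chromosome
    or a gap extends past the end of its sequence.
    """
    result = FilterResult(passed=set())
    for rec in records:
        if rec.n_hits > 1:
            result.discarded["multimapped"] += 1
            continue
        gaps = rec.gaps()
        if gaps:
            if rec.chrom not in genome:
                raise ValueError(
                    f"record {rec.read_id!r} references unknown chromosome {rec.chrom!r}"
                )
            seq = genome[rec.chrom]
            if any(end - start > MAX_INTRON_GAP for start, end in gaps):
                result.discarded["long_gap"] += 1
                continue
            bad = False
            for start, end in gaps:
                if end > len(seq):
                    raise ValueError(
                        f"record {rec.read_id!r}: gap end {end} beyond "
                        f"{rec.chrom!r} length {len(seq)}"
                    )
                if not _splice_motif_ok(seq, start, end):
                    bad = True
                    break
            if bad:
                result.discarded["noncanonical"] += 1
                continue
        result.passed.add(rec.read_id)
    return result


@dataclass
class CellQcReport:
    cell_id: str
    n_genes_detected: int
    total_umis: int
    mito_fraction: float
    passed: bool


def qc_nuclei(
    matrix: UmiMatrix,
    mito_genes: Sequence[str],
    min_genes: int = 200,
    max_genes: int = 2000,
    max_mito_fraction: float = 0.01,
) -> tuple[UmiMatrix, pd.DataFrame]:
    """Discard nuclei with <``min_genes`` or >``max_genes`` detected genes
    or a mitochondrial UMI fraction above ``max_mito_fraction``.

    Returns the subset matrix (counts untouched) and the per-cell report.
    """
    if matrix.n_cells == 0:
        raise ValueError("empty matrix")
    mito_idx = matrix.genes.get_indexer(pd.Index(mito_genes))
    if (mito_idx < 0).any():
        missing = pd.Index(mito_genes)[mito_idx < 0]
        raise ValueError(f"mito genes absent from matrix: {list(missing[:5])}")
    totals = matrix.cell_totals()
    detected = matrix.genes_detected()
    mito_umis = (
        np.asarray(matrix.counts[:, mito_idx].sum(axis=1)).ravel()
        if len(mito_idx)
        else np.zeros(matrix.n_cells)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_umis / np.maximum(totals, 1), 0.0)
    passed = (
        (detected >= min_genes)
        & (detected <= max_genes)
        & (mito_frac <= max_mito_fraction)
    )
    report = pd.DataFrame(
        {
            "cell_id": matrix.cells,
            "n_genes_detected": detected,
            "total_umis": totals.astype(np.int64),
            "mito_fraction": mito_frac,
            "passed": passed,
        }
    ).reset_index(drop=True)
    return matrix.subset_cells(passed), report


def cp10k(matrix: UmiMatrix) -> sp.csr_matrix:
    """Per-cell UMI counts rescaled to counts-per-10,000."""
    totals = matrix.cell_totals()
    if (totals == 0).any():
        zero = matrix.cells[totals == 0]
        raise ValueError(f"cells with zero total UMIs (run QC first): {list(zero[:5])}")
    scale = sp.diags(1e4 / totals)
    return sp.csr_matrix(scale @ matrix.counts)


def pseudobulk_correlation(
    matrix: UmiMatrix,
    bulk_counts: pd.DataFrame,
    phenotype_col: str = "phenotype",
    min_cp10k: float = 1.0,
) -> pd.Series:
    """Pearson r between pooled single-nucleus and bulk profiles per phenotype.

    Both profiles are pooled over replicates, rescaled to CP10K, genes with
    CP10K < ``min_cp10k`` in *both* are dropped, and r is computed on
    log2(CP10K + 1). ``bulk_counts`` is genes × phenotypes.
    """
    shared = matrix.genes.intersection(bulk_counts.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between matrices")
    out = {}
    for ph, cells in matrix.obs.groupby(phenotype_col).groups.items():
        if ph not in bulk_counts.columns:
            raise KeyError(f"phenotype {ph!r} missing from bulk table")
        idx = matrix.obs.index.get_indexer(cells)
        pooled = np.asarray(matrix.counts[idx].sum(axis=0)).ravel()
        sn = pd.Series(pooled, index=matrix.genes).reindex(shared)
        bulk = bulk_counts[ph].reindex(shared).astype(float)
        sn_cp = sn / sn.sum() * 1e4
        bulk_cp = bulk / bulk.sum() * 1e4
        keep = (sn_cp >= min_cp10k) | (bulk_cp >= min_cp10k)
        if keep.sum() < 3:
            raise ValueError(f"fewer than 3 genes survive filtering for {ph!r}")
        x = np.log2(sn_cp[keep] + 1.0)
        y = np.log2(bulk_cp[keep] + 1.0)
        out[ph] = float(np.corrcoef(x, y)[0, 1])
    return pd.Series(out, name="pearson_r")
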
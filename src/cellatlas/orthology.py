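"""Reciprocal-best-hit orthology from bit scores and GO transfer.

Best hits are chosen by maximal bit score after reducing multiple HSPs
of a pair to their maximum; exact ties for a gene's best hit disqualify
that gene (no arbitrary tie-breaking). GO annotation is transferred
through one-to-one orthologue maps in an explicit species priority
order, with an optional best-hit fallback for genes no map covers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

__all__ = ["OrthoMap", "read_blast_tab", "best_hits", "reciprocal_best_hits", "transfer_go"]


@dataclass
class OrthoMap:
    """One-to-one gene pairs between two species."""

    pairs: set[tuple[str, str]]
    species: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        a_genes = [a for a, _ in self.pairs]
        b_genes = [b for _, b in self.pairs]
        if len(set(a_genes)) != len(a_genes) or len(set(b_genes)) != len(b_genes):
            raise ValueError("orthologue map is not one-to-one")

    def as_dict(self) -> dict[str, str]:
        return dict(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def write(self, path: str | Path) -> None:
        pd.DataFrame(sorted(self.pairs), columns=list(self.species)).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def read(cls, path: str | Path) -> "OrthoMap":
        df = pd.read_csv(path, sep="\t")
        return cls(
            set(zip(df.iloc[:, 0], df.iloc[:, 1])),
            species=(df.columns[0], df.columns[1]),
        )


def read_blast_tab(path: str | Path) -> pd.DataFrame:
    """Read a BLAST tabular (outfmt 6) file into (query, subject, bitscore).

    Accepts the standard 12-column layout or a minimal 3-column
    (qseqid, sseqid, bitscore) table.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] >= 12:
        df = df.iloc[:, [0, 1, 11]]
    elif df.shape[1] == 3:
        df = df.iloc[:, [0, 1, 2]]
    else:
        raise ValueError(
            f"expected 3 or ≥12 tab-separated columns, got {df.shape[1]}"
        )
    df.columns = ["query", "subject", "bitscore"]
    df["bitscore"] = df["bitscore"].astype(float)
    return df


def _reduce_hsps(table: pd.DataFrame) -> pd.DataFrame:
    """Keep the maximum bit score per (query, subject) pair."""
    return (
        table.groupby(["query", "subject"], as_index=False)["bitscore"].max()
    )


def best_hits(table: pd.DataFrame) -> dict[str, str]:
    """Best subject per query by bit score; ties exclude the query."""
    reduced = _reduce_hsps(table)
    out: dict[str, str] = {}
    for query, grp in reduced.groupby("query"):
        top = grp["bitscore"].max()
        winners = grp.loc[grp["bitscore"] == top, "subject"]
        if len(winners) == 1:
            out[query] = winners.iloc[0]
    return out


def reciprocal_best_hits(
    a_vs_b: pd.DataFrame,
    b_vs_a: pd.DataFrame,
    species: tuple[str, str] = ("A", "B"),
) -> OrthoMap:
    """One-to-one pairs (x, y) with best(x) = y and best(y) = x."""
    if len(a_vs_b) == 0 or len(b_vs_a) == 0:
        warnings.warn("empty score table; returning empty orthologue map")
        return OrthoMap(set(), species=species)
    fwd = best_hits(a_vs_b)
    rev = best_hits(b_vs_a)
    pairs = {(x, y) for x, y in fwd.items() if rev.get(y) == x}
    return OrthoMap(pairs, species=species)


def transfer_go(
    ortho_maps: Sequence[Mapping[str, str]],
    go_maps: Sequence[Mapping[str, set[str]]],
    fallback_hits: Optional[Mapping[str, str]] = None,
    fallback_go: Optional[Mapping[str, set[str]]] = None,
) -> dict[str, set[str]]:
    """Assign GO sets by species priority, then by best-hit fallback.

    ``ortho_maps[i]`` maps target gene → reference gene of priority-i
    species, whose annotation lives in ``go_maps[i]``. A target gene takes
    the GO set of its orthologue in the highest-priority species with a
    pair; genes left unannotated take their fallback best hit's GO set
    when provided. Genes with no route stay absent from the result.
    """
    if len(ortho_maps) != len(go_maps):
        raise ValueError("ortho_maps and go_maps must align")
    result: dict[str, set[str]] = {}
    for omap, gmap in zip(ortho_maps, go_maps):
        for gene, ref in omap.items():
            if gene in result:
                continue  # a higher-priority species already claimed it
            result[gene] = set(gmap.get(ref, set()))
    if fallback_hits is not None and fallback_go is not None:
        for gene, ref in fallback_hits.items():
            if gene in result:
                continue  # fallback applies only when every priority missed
            result[gene] = set(fallback_go.get(ref, set()))
    return result


def write_go_map(go_map: Mapping[str, set[str]], path: str | Path) -> None:
    rows = [
        {"gene": gene, "go_term": term}
        for gene in sorted(go_map)
        for term in sorted(go_map[gene])
    ]
    pd.DataFrame(rows, columns=["gene", "go_term"]).to_csv(path, sep="\t", index=False)


def read_go_map(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"], df["go_term"]):
        out.setdefault(gene, set()).add(term)
    return out
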
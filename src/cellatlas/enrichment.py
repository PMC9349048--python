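"""GO over-representation with an expression-aware background.

The background is every gene with mean expression above 1 CP10K across
the clusters of interest, excluding the query DEGs themselves. Each GO
term annotated to at least one DEG is tested with a one-sided
(over-representation) Fisher's exact test on the 2×2 table
(DEGs in term / DEGs not / background in term / background not),
BH-adjusted across tested terms. Terms pass with FDR < 0.05 and at
least 2 DEGs annotated.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ClusterExpression, bh_fdr

__all__ = ["go_enrichment"]


def go_enrichment(
    up_degs: Sequence[str],
    expr: ClusterExpression,
    go_map: Mapping[str, set[str]],
    min_cp10k: float = 1.0,
    fdr_level: float = 0.05,
    min_genes: int = 2,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Test GO terms for over-representation among up-regulated DEGs.

    Parameters
    ----------
    up_degs
        Query gene set (up-regulated DEGs of the clusters of interest).
    expr
        Cluster expression over the clusters of interest; defines the
        background via its mean CP10K.
    go_map
        gene → set of GO terms.
    two_sided
        Use a two-sided test instead of the default one-sided
        over-representation test.
    """
    degs = set(up_degs)
    mean_cp10k = expr.mean_cp10k()
    background = set(mean_cp10k.index[mean_cp10k > min_cp10k]) - degs
    if not background:
        raise ValueError("empty background gene set")
    if not any(go_map.get(g) for g in degs):
        raise ValueError("GO map covers none of the query DEGs")

    term_degs: dict[str, int] = {}
    for gene in degs:
        for term in go_map.get(gene, ()):
            term_degs[term] = term_degs.get(term, 0) + 1
    term_bg: dict[str, int] = {term: 0 for term in term_degs}
    for gene in background:
        for term in go_map.get(gene, ()):
            if term in term_bg:
                term_bg[term] += 1

    n_deg, n_bg = len(degs), len(background)
    rows = []
    for term in sorted(term_degs):
        k = term_degs[term]
        m = term_bg[term]
        if two_sided:
            from .composition import fisher_exact_two_sided

            p = fisher_exact_two_sided([[k, n_deg - k], [m, n_bg - m]])
        else:
            # upper tail of Hypergeom(N, term genes, drawn = DEGs)
            p = float(stats.hypergeom.sf(k - 1, n_deg + n_bg, k + m, n_deg))
        rows.append(
            {
                "go_term": term,
                "n_deg_in_term": k,
                "n_deg": n_deg,
                "n_bg_in_term": m,
                "n_bg": n_bg,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["go_term", "n_deg_in_term", "n_deg", "n_bg_in_term", "n_bg", "p_value"],
    )
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    out["significant"] = (out["fdr"] < fdr_level) & (out["n_deg_in_term"] >= min_genes)
    return out
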
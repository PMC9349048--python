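"""Relative-abundance summaries and compositional differential abundance.

The replicate-aware test fits a Dirichlet-multinomial regression with
per-cluster log-concentration intercepts and group effects, the
reference cluster's group effects pinned at zero, and performs a
per-cluster likelihood-ratio test of zero group effect. Decisions
combine a BH-FDR gate with a pooled relative-abundance fold-change gate
(> 1.3-fold at FDR < 0.2 for within-species contrasts; > 2-fold at
FDR < 0.1 is the conventional cross-species setting). A pooled Fisher's
exact test with FDR < 0.001 and the same fold gate serves designs
without replicates, and direction-consistent significant calls across
corresponding clusters of two species are reported as convergent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core import CompositionTable, bh_fdr

__all__ = [
    "relative_abundance",
    "radar_normalize",
    "fold_change",
    "dm_composition_test",
    "fisher_abundance_test",
    "convergence_call",
    "report_fraction",
    "format_fraction",
]


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def relative_abundance(table: CompositionTable, mode: str = "pooled") -> pd.DataFrame:
    """Percentage of cells per cluster.

    ``pooled`` sums counts over each phenotype's replicates before
    dividing (one row per phenotype); ``per_replicate`` computes within
    each sample (one row per sample).
    """
    if mode == "pooled":
        pooled = table.counts.groupby(table.phenotype).sum()
        return pooled.div(pooled.sum(axis=1), axis=0) * 100.0
    if mode == "per_replicate":
        return table.counts.div(table.counts.sum(axis=1), axis=0) * 100.0
    raise ValueError(f"unknown mode {mode!r}")


def radar_normalize(table: CompositionTable) -> pd.DataFrame:
    """Clusters × phenotypes profile in (0, 1].

    Per cluster: mean per-replicate relative abundance within each
    phenotype, divided by the maximum across phenotypes (the top
    phenotype maps to exactly 1). Clusters absent everywhere yield NaN
    with a warning.
    """
    if table.phenotype.nunique() < 2:
        raise ValueError("at least two phenotypes required")
    per_rep = relative_abundance(table, "per_replicate")
    means = per_rep.groupby(table.phenotype).mean()  # phenotypes x clusters
    maxima = means.max(axis=0)
    absent = maxima == 0
    if absent.any():
        warnings.warn(
            f"clusters absent in every sample: {list(maxima.index[absent])}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = means.div(maxima.replace(0, np.nan), axis=1)
    return profile.T  # clusters x phenotypes


def fold_change(rel_a: pd.Series, rel_b: pd.Series) -> pd.DataFrame:
    """Per-cluster fold change of relative abundances with direction.

    ``fold`` is the larger abundance over the smaller (``inf`` when one
    side is zero, so complete absence passes any finite gate); direction
    is +1 when group a is higher, −1 when lower, 0 on ties. Both sides
    zero → NaN fold, direction 0.
    """
    if not rel_a.index.equals(rel_b.index):
        raise ValueError("fold change requires identical cluster indexes")
    a = rel_a.to_numpy(dtype=float)
    b = rel_b.to_numpy(dtype=float)
    direction = np.sign(a - b).astype(int)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(a >= b, a / b, b / a)
    fold = np.where((a == 0) & (b == 0), np.nan, fold)
    return pd.DataFrame({"fold": fold, "direction": direction}, index=rel_a.index)


def report_fraction(n_pass: int, n_total: int, decimals: int = 1) -> float:
    """100 × n_pass / n_total, rounded half-away-from-zero."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_pass <= n_total:
        raise ValueError("n_pass must lie in [0, n_total]")
    quantum = Decimal(1).scaleb(-decimals)
    value = Decimal(100 * n_pass) / Decimal(n_total)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def format_fraction(n_pass: int, n_total: int, decimals: int = 1) -> str:
    value = report_fraction(n_pass, n_total, decimals)
    if float(value).is_integer():
        return f"{int(value)}%"
    return f"{value:.{decimals}f}%"


# ---------------------------------------------------------------------------
# Dirichlet-multinomial likelihood-ratio test
# ---------------------------------------------------------------------------


def _dm_negloglik_grad(
    params: np.ndarray,
    counts: np.ndarray,
    group_idx: np.ndarray,
    n_groups: int,
    free_effect: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Negative DM log-likelihood (sans multinomial constant) + gradient.

    ``params`` packs K intercepts followed by the free group-effect
    entries (row-major over groups 1..G-1 × clusters flagged in
    ``free_effect``). Concentrations are exp of the linear predictor.
    """
    s, k = counts.shape
    b0 = params[:k]
    effects = np.zeros((n_groups - 1, k))
    if free_effect.any():
        effects[:, free_effect] = params[k:].reshape(n_groups - 1, -1)
    eta = np.tile(b0, (s, 1))
    for g in range(1, n_groups):
        eta[group_idx == g] += effects[g - 1]
    alpha = np.exp(eta)
    a_tot = alpha.sum(axis=1)
    n_tot = counts.sum(axis=1)
    ll = (
        special.gammaln(a_tot).sum()
        - special.gammaln(n_tot + a_tot).sum()
        + special.gammaln(counts + alpha).sum()
        - special.gammaln(alpha).sum()
    )
    dl_dalpha = (
        special.psi(a_tot)[:, None]
        - special.psi(n_tot + a_tot)[:, None]
        + special.psi(counts + alpha)
        - special.psi(alpha)
    )
    dl_deta = dl_dalpha * alpha
    grad_b0 = dl_deta.sum(axis=0)
    grads = [grad_b0]
    for g in range(1, n_groups):
        grads.append(dl_deta[group_idx == g].sum(axis=0)[free_effect])
    return -ll, -np.concatenate(grads)


def _fit_dm(
    counts: np.ndarray,
    group_idx: np.ndarray,
    n_groups: int,
    free_effect: np.ndarray,
) -> tuple[float, optimize.OptimizeResult]:
    """Maximize the DM likelihood; returns (max log-likelihood, result)."""
    s, k = counts.shape
    props = (counts + 0.5) / (counts + 0.5).sum(axis=1, keepdims=True)
    b0_init = np.log(props.mean(axis=0) * 50.0)
    x0 = np.concatenate([b0_init, np.zeros((n_groups - 1) * int(free_effect.sum()))])
    # box bounds keep concentrations finite when the data carry no
    # overdispersion (identical samples drive the MLE to the boundary)
    res = optimize.minimize(
        _dm_negloglik_grad,
        x0,
        args=(counts, group_idx, n_groups, free_effect),
        jac=True,
        method="L-BFGS-B",
        bounds=[(-20.0, 20.0)] * x0.size,
        options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-8},
    )
    return -res.fun, res


def _check_converged(res: optimize.OptimizeResult, label: str) -> None:
    """Accept optimizer exits that sit at a flat optimum or box boundary.

    Identical or near-identical samples drive the concentration to the
    bound, where L-BFGS-B reports an abnormal line search despite a
    negligible gradient; only a genuinely unconverged fit is an error.
    """
    if res.success:
        return
    grad = np.abs(np.asarray(res.jac)).max()
    if grad < 1e-3 * (1.0 + abs(float(res.fun))):
        return
    raise RuntimeError(f"{label} did not converge: {res.message} (|grad|={grad:.3g})")


def auto_reference(table: CompositionTable, samples: Optional[Sequence] = None) -> str:
    """Cluster detected in every sample with minimal CV of relative abundance."""
    counts = table.counts if samples is None else table.counts.loc[samples]
    rel = counts.div(counts.sum(axis=1), axis=0)
    ubiquitous = (counts > 0).all(axis=0)
    if not ubiquitous.any():
        raise ValueError("no cluster is detected in every sample")
    cv = rel.std(axis=0, ddof=1) / rel.mean(axis=0)
    cv = cv[ubiquitous.index[ubiquitous]]
    return cv.sort_index().idxmin()


def dm_composition_test(
    table: CompositionTable,
    groups: tuple[str, str],
    reference: str = "auto",
    fdr_level: float = 0.2,
    min_fold: float = 1.3,
) -> pd.DataFrame:
    """Replicate-aware compositional test between two phenotypes.

    Likelihood-ratio test of zero group effect per non-reference cluster
    (df = 1), BH-adjusted across clusters; a cluster is significant when
    FDR < ``fdr_level`` and the pooled relative-abundance fold change
    exceeds ``min_fold``. Clusters with zero counts in every selected
    sample are excluded with a warning.
    """
    g1, g2 = groups
    mask = table.phenotype.isin([g1, g2])
    for g in groups:
        if (table.phenotype == g).sum() < 2:
            raise ValueError(f"group {g!r} needs at least two samples")
    counts_df = table.counts.loc[mask.to_numpy()]
    pheno = table.phenotype[mask.to_numpy()]
    allzero = counts_df.sum(axis=0) == 0
    if allzero.any():
        warnings.warn(f"excluding all-zero clusters: {list(counts_df.columns[allzero])}")
        counts_df = counts_df.loc[:, ~allzero]
    clusters = list(counts_df.columns)
    if reference == "auto":
        sub = CompositionTable(counts_df, pheno)
        reference = auto_reference(sub)
    elif reference not in clusters:
        raise ValueError(f"unknown reference cluster {reference!r}")
    if (counts_df[reference] == 0).any():
        raise ValueError(
            f"reference cluster {reference!r} is not detected in every sample"
        )

    counts = counts_df.to_numpy(dtype=float)
    group_idx = (pheno == g2).to_numpy().astype(int)
    k = len(clusters)
    ref_pos = clusters.index(reference)
    free_full = np.ones(k, dtype=bool)
    free_full[ref_pos] = False

    ll_full, res_full = _fit_dm(counts, group_idx, 2, free_full)
    _check_converged(res_full, "full model")

    records = []
    pooled = counts_df.groupby(pheno.to_numpy()).sum()
    rel1 = pooled.loc[g1] / pooled.loc[g1].sum()
    rel2 = pooled.loc[g2] / pooled.loc[g2].sum()
    fc = fold_change(rel1, rel2)
    for j, cluster in enumerate(clusters):
        if cluster == reference:
            records.append((cluster, np.nan, np.nan))
            continue
        free = free_full.copy()
        free[j] = False
        ll_null, res_null = _fit_dm(counts, group_idx, 2, free)
        _check_converged(res_null, f"null fit for cluster {cluster!r}")
        stat = max(2.0 * (ll_full - ll_null), 0.0)
        records.append((cluster, stat, stats.chi2.sf(stat, df=1)))
    out = pd.DataFrame(records, columns=["cluster", "statistic", "p_value"]).set_index(
        "cluster"
    )
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    out["fold"] = fc["fold"]
    out["direction"] = fc["direction"]
    out["reference"] = out.index == reference
    fold_ok = out["fold"].to_numpy() > min_fold  # inf passes, NaN fails
    out["significant"] = (out["fdr"] < fdr_level).fillna(False) & fold_ok
    return out


# ---------------------------------------------------------------------------
# pooled Fisher route and convergence
# ---------------------------------------------------------------------------


def fisher_exact_two_sided(table2x2: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p: total probability of tables (at fixed
    margins) no more probable than the observed one.

    Inclusion is decided by exact integer comparison of hypergeometric
    numerators, so ties are handled without floating-point tolerance.
    """
    (a, b), (c, d) = table2x2
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n_total == 0:
        return 1.0
    lo = max(0, row1 + col1 - n_total)
    hi = min(row1, col1)
    obs_num = math.comb(col1, a) * math.comb(n_total - col1, row1 - a)
    total = math.comb(n_total, row1)
    acc = 0
    for k in range(lo, hi + 1):
        num = math.comb(col1, k) * math.comb(n_total - col1, row1 - k)
        if num <= obs_num:
            acc += num
    return min(acc / total, 1.0)


def fisher_abundance_test(
    counts_a: pd.Series,
    counts_b: pd.Series,
    fdr_cut: float = 0.001,
    min_fold: float = 1.3,
) -> pd.DataFrame:
    """Pooled two-group Fisher's exact test per cluster with the stated gates."""
    if not counts_a.index.equals(counts_b.index):
        raise ValueError("cluster indexes must match")
    tot_a, tot_b = int(counts_a.sum()), int(counts_b.sum())
    if tot_a == 0 or tot_b == 0:
        raise ValueError("both groups need at least one cell")
    pvals = []
    for cluster in counts_a.index:
        ia, ib = int(counts_a[cluster]), int(counts_b[cluster])
        pvals.append(
            fisher_exact_two_sided([[ia, tot_a - ia], [ib, tot_b - ib]])
        )
    out = pd.DataFrame({"p_value": pvals}, index=counts_a.index)
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    fc = fold_change(counts_a / tot_a, counts_b / tot_b)
    out["fold"] = fc["fold"]
    out["direction"] = fc["direction"]
    out["significant"] = (out["fdr"] < fdr_cut) & (out["fold"] > min_fold)
    return out


def convergence_call(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    correspondence: pd.DataFrame,
) -> set[tuple[str, str]]:
    """Cluster pairs with significant, direction-consistent change in both
    species.

    ``correspondence`` needs ``source``/``target`` columns (e.g. from
    :func:`cellatlas.crossmap.correspondence_network`); pairs whose
    clusters are missing from either call table are skipped with a
    warning.
    """
    convergent: set[tuple[str, str]] = set()
    for _, edge in correspondence.iterrows():
        src, tgt = edge["source"], edge["target"]
        if src not in calls_a.index or tgt not in calls_b.index:
            warnings.warn(f"no abundance call for pair ({src!r}, {tgt!r}); skipped")
            continue
        ra, rb = calls_a.loc[src], calls_b.loc[tgt]
        if (
            bool(ra["significant"])
            and bool(rb["significant"])
            and ra["direction"] == rb["direction"]
            and ra["direction"] != 0
        ):
            convergent.add((src, tgt))
    return convergent
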
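"""Agglomerative clustering on precomputed dissimilarities.

Implements the classic Ward update (the non-squared "Ward.D" variant of
the Lance–Williams recurrence) directly on an arbitrary dissimilarity
matrix, which is what correlation-distance dendrograms of cluster
profiles require. SciPy's ``linkage(method="ward")`` implements the
squared (D2) variant, hence the small bespoke implementation here.
Merge order is made deterministic by breaking ties on the smallest leaf
label of each candidate pair, which also makes the topology invariant
to input row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Node",
    "ward_tree",
    "correlation_distance",
    "newick",
    "clades",
    "bootstrap_support",
]


@dataclass
class Node:
    """Binary dendrogram node; leaves carry ``label``, internals a height."""

    height: float = 0.0
    label: Optional[str] = None
    left: Optional["Node"] = None
    right: Optional["Node"] = None
    support: Optional[float] = None
    leaves: frozenset = field(default_factory=frozenset)

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def __iter__(self):
        if self.is_leaf:
            yield self
        else:
            yield from self.left
            yield from self.right


def correlation_distance(profiles: np.ndarray) -> np.ndarray:
    """1 − Pearson correlation between rows; zero-variance rows → distance 1."""
    x = np.asarray(profiles, dtype=float)
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    dist = 1.0 - corr
    dist[(sd > 0)[:, None] & (sd > 0)[None, :] & np.isclose(dist, 0.0)] = 0.0
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, None)


def ward_tree(dist: np.ndarray, labels: Sequence[str]) -> Node:
    """Agglomerate with the classic Ward (Lance–Williams, unsquared) update.

    Parameters
    ----------
    dist
        Square symmetric dissimilarity matrix.
    labels
        One label per row; must be unique.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    labels = list(labels)
    if len(labels) != n:
        raise ValueError("labels must match the distance matrix size")
    if len(set(labels)) != n:
        raise ValueError("labels must be unique")
    if n == 1:
        return Node(label=labels[0], leaves=frozenset(labels))

    nodes = [Node(label=lab, leaves=frozenset([lab])) for lab in labels]
    sizes = [1] * n
    keys = [lab for lab in labels]  # min leaf label, for deterministic ties
    d = dist.astype(float).copy()
    active = list(range(n))

    while len(active) > 1:
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1 :]:
                cand = (d[i, j], *sorted((keys[i], keys[j])))
                if best is None or cand < best[0]:
                    best = (cand, i, j)
        _, i, j = best
        height = d[i, j]
        left, right = sorted((i, j), key=lambda k: keys[k])
        merged = Node(
            height=height,
            left=nodes[left],
            right=nodes[right],
            leaves=nodes[i].leaves | nodes[j].leaves,
        )
        ni, nj = sizes[i], sizes[j]
        # Lance-Williams ward.D update toward every other active cluster
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            dk = (
                (ni + nk) * d[i, k] + (nj + nk) * d[j, k] - nk * d[i, j]
            ) / (ni + nj + nk)
            d[i, k] = d[k, i] = dk
        nodes[i] = merged
        sizes[i] = ni + nj
        keys[i] = min(keys[i], keys[j])
        active.remove(j)

    return nodes[active[0]]


def clades(tree: Node) -> set[frozenset]:
    """Leaf sets of all internal nodes (including the root)."""
    out: set[frozenset] = set()

    def walk(node: Node) -> None:
        if node.is_leaf:
            return
        out.add(node.leaves)
        walk(node.left)
        walk(node.right)

    walk(tree)
    return out


def newick(tree: Node, with_support: bool = False) -> str:
    """Render as a rooted Newick string with branch lengths."""

    def render(node: Node, parent_height: float) -> str:
        length = max(parent_height - node.height, 0.0)
        if node.is_leaf:
            return f"{_escape(node.label)}:{length:.6g}"
        inner = f"({render(node.left, node.height)},{render(node.right, node.height)})"
        tag = ""
        if with_support and node.support is not None:
            tag = f"{node.support:.2f}"
        return f"{inner}{tag}:{length:.6g}"

    if tree.is_leaf:
        return f"{_escape(tree.label)};"
    body = f"({render(tree.left, tree.height)},{render(tree.right, tree.height)})"
    if with_support and tree.support is not None:
        body += f"{tree.support:.2f}"
    return body + ";"


def _escape(label: str) -> str:
    if any(c in label for c in "(),:;' \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def bootstrap_support(
    profiles: pd.DataFrame,
    n_reps: int,
    rng: np.random.Generator,
    dist_fn: Callable[[np.ndarray], np.ndarray] = correlation_distance,
) -> Node:
    """Ward tree of profile rows with feature-bootstrap branch support.

    Branch support of an internal node is the fraction of gene-resampled
    replicate trees that contain the same leaf set as a clade.
    """
    labels = list(profiles.index)
    values = profiles.to_numpy(dtype=float)
    tree = ward_tree(dist_fn(values), labels)
    if n_reps <= 0:
        return tree
    counts: dict[frozenset, int] = {c: 0 for c in clades(tree)}
    n_genes = values.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, n_genes, size=n_genes)
        rep = ward_tree(dist_fn(values[:, cols]), labels)
        for c in clades(rep):
            if c in counts:
                counts[c] += 1

    def attach(node: Node) -> None:
        if node.is_leaf:
            return
        node.support = counts[node.leaves] / n_reps
        attach(node.left)
        attach(node.right)

    attach(tree)
    return tree
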
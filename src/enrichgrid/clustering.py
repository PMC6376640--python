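"""Condition distances and hierarchical clustering.

Three dissimilarities between enrichment profiles are provided:

* **Jaccard**: ``1 - |Terms(k) n Terms(l)| / |Terms(k) u Terms(l)|`` over
  the per-condition sets of enriched terms (both-empty pairs get 0).
* **Euclidean on common terms**: for each pair, the Euclidean distance over
  the cells of terms enriched in *both* conditions; pairs sharing no term
  are assigned the maximum finite distance in the matrix (maximally
  dissimilar).  Because each pair uses its own subvector this is not a
  metric, and no triangle inequality is assumed anywhere.
* **Combined**: the mean ``(D + DE01)/2`` of the Jaccard matrix and the
  Euclidean matrix min-max scaled to [0, 1] over its off-diagonal entries.

Agglomerative clustering (complete / single / ward linkage) runs on the
precomputed matrix via scipy; results are deterministic for a given input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Set

import numpy as np
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform

from .errors import DomainError, InputError
from .matrices import TermMatrix, term_sets

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "jaccard_distance",
    "euclidean_common_distance",
    "combined_distance",
    "hierarchical_cluster",
    "cut_clusters",
]

LINKAGES = ("complete", "single", "ward")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise condition dissimilarities with zero diagonal."""

    ids: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise InputError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise InputError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise InputError("distance matrix diagonal is not zero")

    def condensed(self) -> np.ndarray:
        # force exact symmetry/diagonal for squareform
        v = (self.values + self.values.T) / 2
        np.fill_diagonal(v, 0.0)
        return squareform(v, checks=False)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t"
        )


def jaccard_distance(sets: Mapping[str, Set[str]]) -> DistanceMatrix:
    """1 minus the Jaccard index of per-condition enriched-term sets.

    A pair of conditions that are both empty is treated as identical (0).
    """
    ids = list(sets)
    if len(ids) < 2:
        raise DomainError("need at least 2 conditions")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = set(sets[ids[i]]), set(sets[ids[j]])
            union = a | b
            d[i, j] = d[j, i] = 1 - len(a & b) / len(union) if union else 0.0
    return DistanceMatrix(ids=ids, values=d, kind="jaccard")


def euclidean_common_distance(tm: TermMatrix) -> DistanceMatrix:
    """Euclidean distance over terms enriched in both conditions of a pair.

    Pairs with an empty common set receive the maximum finite distance found
    among the other pairs; if no pair shares a term, all off-diagonal
    entries are set to 1 with a warning.
    """
    ids = tm.conditions
    if len(ids) < 2:
        raise DomainError("need at least 2 conditions")
    x = tm.data.to_numpy()
    n = len(ids)
    d = np.full((n, n), np.nan)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            comm = ~np.isnan(x[i]) & ~np.isnan(x[j])
            if comm.any():
                d[i, j] = d[j, i] = float(
                    np.sqrt(np.sum((x[i, comm] - x[j, comm]) ** 2))
                )
    off = d[~np.eye(n, dtype=bool)]
    if np.all(np.isnan(off)):
        warnings.warn(
            "no condition pair shares an enriched term; distances degenerate to 1",
            stacklevel=2,
        )
        d[np.isnan(d)] = 1.0
    elif np.any(np.isnan(d)):
        d[np.isnan(d)] = np.nanmax(off)
    return DistanceMatrix(ids=ids, values=d, kind="euclidean_common")


def combined_distance(
    d_jac: DistanceMatrix, d_euc: DistanceMatrix
) -> DistanceMatrix:
    """Mean of the Jaccard matrix and the [0,1]-scaled Euclidean matrix.

    Scaling is min-max over off-diagonal entries; a constant Euclidean
    matrix scales to all zeros.
    """
    if d_jac.ids != d_euc.ids:
        raise InputError("distance matrices have different condition orderings")
    n = len(d_jac.ids)
    off = ~np.eye(n, dtype=bool)
    de = d_euc.values.copy()
    lo, hi = de[off].min(), de[off].max()
    de01 = np.zeros_like(de)
    if hi > lo:
        de01[off] = (de[off] - lo) / (hi - lo)
    m = (d_jac.values + de01) / 2
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(ids=d_jac.ids, values=m, kind="combined")


@dataclass
class Dendrogram:
    """Agglomerative merge tree over conditions.

    ``merges`` is a scipy linkage matrix; ``leaf_order`` lists condition ids
    in dendrogram display order.
    """

    ids: list[str]
    merges: np.ndarray
    linkage: str

    @property
    def leaf_order(self) -> list[str]:
        return [self.ids[i] for i in sch.leaves_list(self.merges)]

    def to_newick(self) -> str:
        """Serialise the merge tree as Newick with height-difference branches."""
        n = len(self.ids)
        heights = {i: 0.0 for i in range(n)}
        texts = {i: _escape(self.ids[i]) for i in range(n)}
        for step, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            node = n + step
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            texts[node] = f"({texts[a]}:{la:g},{texts[b]}:{lb:g})"
            heights[node] = float(h)
        return texts[n + len(self.merges) - 1] + ";"


def _escape(label: str) -> str:
    if any(c in label for c in " (),:;'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def hierarchical_cluster(d: DistanceMatrix, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering on a precomputed dissimilarity matrix.

    ``ward`` follows the Ward-on-dissimilarity convention (Lance-Williams
    update on squared distances of the supplied matrix).
    """
    if linkage not in LINKAGES:
        raise DomainError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    if len(d.ids) < 2:
        raise DomainError("need at least 2 conditions to cluster")
    merges = sch.linkage(d.condensed(), method=linkage)
    return Dendrogram(ids=list(d.ids), merges=merges, linkage=linkage)


def cut_clusters(dend: Dendrogram, k: int) -> dict[str, int]:
    """Cut the tree into exactly ``k`` clusters, labelled 1..k in leaf order."""
    n = len(dend.ids)
    if not 1 <= k <= n:
        raise DomainError(f"k must lie in [1, {n}], got {k}")
    raw = sch.cut_tree(dend.merges, n_clusters=k).ravel()
    # relabel so that clusters are numbered by first appearance in leaf order
    relabel: dict[int, int] = {}
    for leaf in sch.leaves_list(dend.merges):
        c = int(raw[leaf])
        if c not in relabel:
            relabel[c] = len(relabel) + 1
    return {dend.ids[i]: relabel[int(raw[i])] for i in range(n)}
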
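"""Independent reference implementations used only by the tests.

Each oracle re-derives an expected result by a route the package does not
use: combinatorial sums instead of scipy's distribution machinery, explicit
path enumeration instead of ancestor-set logic, a literal O(N^3)
Lance-Williams agglomeration instead of scipy's linkage, and a hand-rolled
Benjamini-Hochberg step-up instead of statsmodels.
"""

from __future__ import annotations

from math import comb, sqrt

import networkx as nx
import numpy as np


def hypergeom_tail(overlap: int, term_size: int, query_size: int, universe_size: int) -> float:
    """P(X >= overlap) by direct summation of the hypergeometric pmf."""
    total = comb(universe_size, query_size)
    acc = 0
    for i in range(overlap, min(term_size, query_size) + 1):
        if query_size - i <= universe_size - term_size:
            acc += comb(term_size, i) * comb(universe_size - term_size, query_size - i)
    return acc / total


def bh_stepup(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values, hand-executed step-up."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj_sorted = [pvalues[order[i]] * m / (i + 1) for i in range(m)]
    for i in range(m - 2, -1, -1):  # enforce monotonicity from the largest p
        adj_sorted[i] = min(adj_sorted[i], adj_sorted[i + 1])
    adj = [0.0] * m
    for rank, i in enumerate(order):
        adj[i] = min(1.0, adj_sorted[rank])
    return adj


def memberships_by_path_enumeration(graph: nx.DiGraph, root: str) -> dict[str, set[tuple[str, str]]]:
    """Expected three-level memberships from brute-force path enumeration.

    For every simple path ``node -> ... -> root`` the node receives the
    pair implied by the path's two nodes nearest the root: ``(self, self)``
    for 1-edge paths, ``(parent, self)`` for 2-edge paths, and
    ``(depth-1 ancestor, depth-2 ancestor)`` for longer ones.
    """
    out: dict[str, set[tuple[str, str]]] = {}
    for node in graph.nodes:
        if node == root:
            continue
        pairs = set()
        for path in nx.all_simple_paths(graph, node, root):
            if len(path) == 2:
                pairs.add((node, node))
            elif len(path) == 3:
                pairs.add((path[1], node))
            else:
                pairs.add((path[-2], path[-3]))
        if pairs:
            out[node] = pairs
    return out


def random_rooted_dag(rng: np.random.Generator, max_nodes: int = 200) -> tuple[nx.DiGraph, str]:
    """Layered random DAG with child -> parent edges and a single root.

    Nodes may connect to any shallower layer (not just the previous one),
    so terms are reachable at several depths; out-degree is capped at 2 to
    keep brute-force path enumeration cheap.
    """
    n_layers = int(rng.integers(2, 7))
    root = "root"
    g = nx.DiGraph()
    g.add_node(root)
    layers: list[list[str]] = [[root]]
    remaining = int(rng.integers(5, max_nodes))
    for layer_idx in range(1, n_layers + 1):
        width = int(rng.integers(1, max(2, remaining // (n_layers - layer_idx + 1)) + 1))
        width = min(width, remaining)
        if width == 0:
            break
        layer = [f"n{layer_idx}_{i}" for i in range(width)]
        shallower = [n for lay in layers for n in lay]
        for node in layer:
            n_parents = int(rng.integers(1, 3))
            parents = rng.choice(len(shallower), size=min(n_parents, len(shallower)), replace=False)
            for p in parents:
                g.add_edge(node, shallower[p])
        layers.append(layer)
        remaining -= width
    return g, root


def naive_agglomerate(dist: np.ndarray, method: str) -> list[tuple[frozenset[int], float]]:
    """Greedy O(N^3) agglomerative clustering via Lance-Williams updates.

    Returns the merge tree as ``(leaf set, merge height)`` per internal
    node.  Ties break on the lexicographically smallest active pair.
    """
    n = dist.shape[0]
    clusters: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    d = {(i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[frozenset[int], float]] = []
    next_id = n
    while len(clusters) > 1:
        (i, j), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        ni, nj = len(clusters[i]), len(clusters[j])
        merged = clusters[i] | clusters[j]
        merges.append((merged, h))
        others = [k for k in clusters if k not in (i, j)]
        for k in others:
            dik = d[tuple(sorted((i, k)))]
            djk = d[tuple(sorted((j, k)))]
            nk = len(clusters[k])
            if method == "single":
                dnew = min(dik, djk)
            elif method == "complete":
                dnew = max(dik, djk)
            elif method == "ward":
                dnew = sqrt(
                    ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * h**2)
                    / (ni + nj + nk)
                )
            else:
                raise ValueError(method)
            d[(min(k, next_id), max(k, next_id))] = dnew
        for key in list(d):
            if i in key or j in key:
                del d[key]
        del clusters[i], clusters[j]
        clusters[next_id] = merged
        next_id += 1
    return merges


def scipy_tree(Z: np.ndarray, n: int) -> list[tuple[frozenset[int], float]]:
    """Internal nodes of a scipy linkage matrix as (leaf set, height)."""
    leafsets: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    out = []
    for step, (a, b, h, _) in enumerate(Z):
        merged = leafsets[int(a)] | leafsets[int(b)]
        leafsets[n + step] = merged
        out.append((merged, float(h)))
    return out
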
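"""Brute-force reference implementations for cross-validation.

These are deliberately naive, independent routes to the same objects the
fast sweep computes: a Floyd-Warshall-style O(n^3) closure for the
subdominant ultrametric, exhaustive enumeration of all n^(n-2) labelled
spanning trees for the all-MST edge union, and exhaustive simple-path
enumeration for pairwise minimax values. They ship in the package (not
only in the test suite) so users can cross-validate on their own data;
the exponential ones are guarded by instance-size caps.
"""

from __future__ import annotations

from itertools import permutations, product

import numpy as np

from .core import SubdominantUltrametric, _edge_key
from .errors import CapabilityError
from .io import LabeledDissimilarity

#: size caps of the exhaustive oracles
MAX_N_TREES = 9
MAX_N_PATHS = 8


def bottleneck_closure(D: LabeledDissimilarity) -> SubdominantUltrametric:
    """Subdominant ultrametric by minimax dynamic-programming closure, O(n^3).

    Initialize M := W with zero diagonal, then for each pivot w relax
    ``M(u,v) := min(M(u,v), max(M(u,w), M(w,v)))`` -- the minimax analogue of
    Floyd-Warshall shortest paths.
    """
    m = D.matrix.copy()
    np.fill_diagonal(m, 0.0)
    n = D.n
    for w in range(n):
        # in-place is safe: row/column w are fixed points of pivot w
        np.minimum(m, np.maximum(m[:, w : w + 1], m[w : w + 1, :]), out=m)
    return SubdominantUltrametric(D.labels, m)


def _prufer_edges(seq: tuple[int, ...], n: int) -> list[tuple[int, int]]:
    """Decode a Prüfer sequence over {0..n-1} into the n-1 tree edges."""
    degree = [1] * n
    for x in seq:
        degree[x] += 1
    edges = []
    ptr = 0
    while degree[ptr] != 1:
        ptr += 1
    leaf = ptr
    for x in seq:
        edges.append((leaf, x))
        degree[x] -= 1
        if degree[x] == 1 and x < ptr:
            leaf = x
        else:
            ptr += 1
            while degree[ptr] != 1:
                ptr += 1
            leaf = ptr
    edges.append((leaf, n - 1))
    return edges


def all_spanning_trees(n: int):
    """Yield the edge lists of all n^(n-2) labelled spanning trees on n >= 2."""
    if n == 2:
        yield [(0, 1)]
        return
    for seq in product(range(n), repeat=n - 2):
        yield _prufer_edges(seq, n)


def all_mst_edge_union(D: LabeledDissimilarity, rtol: float = 1e-12) -> frozenset:
    """Union of the edge sets of all minimum spanning trees, by enumeration.

    Every labelled spanning tree of the complete graph is generated via its
    Prüfer sequence, so the search is exhaustive over n^(n-2) trees; capped
    at n <= 9.
    """
    n = D.n
    if n > MAX_N_TREES:
        raise CapabilityError(
            f"exhaustive tree enumeration capped at n={MAX_N_TREES}, got {n}"
        )
    W = D.matrix
    labels = D.labels
    best = float("inf")
    union: set[tuple[int, int]] = set()
    for edges in all_spanning_trees(n):
        total = 0.0
        for i, j in edges:
            total += W[i, j]
        tol = rtol * max(1.0, abs(best) if best < float("inf") else 1.0)
        if total < best - tol:
            best = total
            union = set(edges)
        elif total <= best + tol:
            union.update(edges)
    return frozenset(_edge_key(labels[i], labels[j]) for i, j in union)


def min_bottleneck_by_paths(D: LabeledDissimilarity, u: str, v: str) -> float:
    """min over all simple u-v paths of the heaviest edge on the path.

    Enumerates every ordered subset of the remaining vertices as the
    interior of the path; capped at n <= 8.
    """
    n = D.n
    if n > MAX_N_PATHS:
        raise CapabilityError(
            f"exhaustive path enumeration capped at n={MAX_N_PATHS}, got {n}"
        )
    i, j = D.index(u), D.index(v)
    if i == j:
        return 0.0
    W = D.matrix
    others = [k for k in range(n) if k not in (i, j)]
    best = W[i, j]  # the direct edge
    for k in range(1, len(others) + 1):
        for interior in permutations(others, k):
            path = (i, *interior, j)
            b = max(W[a, b_] for a, b_ in zip(path, path[1:]))
            if b < best:
                best = b
    return float(best)
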
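"""Artificial (median / Steiner) vertex insertion.

A triangle u-w-y in the network whose perimeter exceeds a threshold is
replaced by a star through a new vertex x placed at the median of the
three corners. The star edge lengths are the Gromov products

    d(x,u) = (d(u,w) + d(u,y) - d(w,y)) / 2    (and cyclically),

the unique assignment under which the two-edge path through x reproduces
each original pairwise distance exactly while the total edge weight drops
from the perimeter to half the perimeter. Biologically, x models a
missing or ancestral haplotype interior to the three observed ones.

Candidate triangles are ranked canonically (perimeter descending, ties
by label triple), so the augmentation does not depend on edge input
order; triangles that lost an edge to an earlier insertion are skipped,
and artificial vertices never seed new candidates (single pass).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

from .core import UltrametricNetwork, _edge_key
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Triangle:
    """A candidate 3-cycle: sorted corner labels and its perimeter."""

    corners: tuple[str, str, str]
    perimeter: float


@dataclass(frozen=True)
class AugmentedNetwork:
    """A network after artificial-vertex insertion.

    ``original_labels`` are the input taxa; ``artificial_labels`` the
    generated ``N1``, ``N2``, ... in creation order; ``provenance`` maps each
    artificial vertex to the corner triple of the triangle it replaced.
    """

    original_labels: tuple[str, ...]
    artificial_labels: tuple[str, ...]
    edges: dict[tuple[str, str], float]
    provenance: dict[str, tuple[str, str, str]] = field(default_factory=dict)
    delta: float = 0.0
    threshold: float = 0.0

    @property
    def labels(self) -> tuple[str, ...]:
        return self.original_labels

    @property
    def all_labels(self) -> tuple[str, ...]:
        return self.original_labels + self.artificial_labels

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    def total_weight(self) -> float:
        return float(sum(self.edges.values()))

    def degree(self, label: str) -> int:
        return sum(label in e for e in self.edges)

    def path_distance(self, u: str, v: str) -> float:
        """Shortest path distance (sum of weights) between two vertices."""
        import heapq

        dist = {u: 0.0}
        heap = [(0.0, u)]
        adj: dict[str, list[tuple[str, float]]] = {}
        for (a, b), w in self.edges.items():
            adj.setdefault(a, []).append((b, w))
            adj.setdefault(b, []).append((a, w))
        while heap:
            d, x = heapq.heappop(heap)
            if x == v:
                return d
            if d > dist.get(x, float("inf")):
                continue
            for y, w in adj.get(x, ()):
                nd = d + w
                if nd < dist.get(y, float("inf")):
                    dist[y] = nd
                    heapq.heappush(heap, (nd, y))
        return float("inf")


def find_candidate_triangles(
    network: UltrametricNetwork, threshold: float
) -> list[Triangle]:
    """All 3-cycles of the network with perimeter strictly above ``threshold``.

    Sorted canonically: perimeter descending, ties by the lexicographic
    triple of sorted corner labels.
    """
    edges = network.edges
    adj = network.adjacency()
    out: list[Triangle] = []
    for u, v, w in combinations(sorted(network.labels), 3):
        if v in adj[u] and w in adj[u] and w in adj[v]:
            perim = edges[_edge_key(u, v)] + edges[_edge_key(u, w)] + edges[_edge_key(v, w)]
            if perim > threshold:
                out.append(Triangle((u, v, w), float(perim)))
    out.sort(key=lambda t: (-t.perimeter, t.corners))
    return out


def median_distances(
    d_uw: float, d_uy: float, d_wy: float
) -> tuple[float, float, float]:
    """Star edge lengths from the median x of a triangle (u, w, y).

    Solves ``d(x,u)+d(x,w) = d(u,w)`` and cyclic permutations; the solutions
    are the Gromov products

        d(x,u) = (d_uw + d_uy - d_wy) / 2,
        d(x,w) = (d_uw + d_wy - d_uy) / 2,
        d(x,y) = (d_uy + d_wy - d_uw) / 2.

    The star's total weight is half the triangle perimeter. A violated
    triangle inequality shows up as a negative output; callers treat any
    nonpositive output as a degenerate triangle and skip it.
    """
    d_xu = (d_uw + d_uy - d_wy) / 2.0
    d_xw = (d_uw + d_wy - d_uy) / 2.0
    d_xy = (d_uy + d_wy - d_uw) / 2.0
    return d_xu, d_xw, d_xy


def insert_artificial_vertices(
    network: UltrametricNetwork, threshold: float
) -> AugmentedNetwork:
    """Replace heavy triangles by median stars, in canonical order.

    Candidates are the triangles of the input network whose perimeter
    strictly exceeds ``threshold``, processed by perimeter descending. A
    triangle is replaced only if all three of its edges are still present
    (an earlier insertion may have consumed a shared edge). Degenerate
    triangles -- a median edge of nonpositive length -- are skipped with a
    warning, preserving the identity of the input taxa. Artificial vertices
    are named ``N1``, ``N2``, ... in creation order and do not seed new
    candidate triangles.
    """
    if threshold < 0:
        raise ValidationError(f"threshold must be nonnegative, got {threshold}")
    edges = dict(network.edges)
    artificial: list[str] = []
    provenance: dict[str, tuple[str, str, str]] = {}
    for tri in find_candidate_triangles(network, threshold):
        u, w, y = tri.corners
        k_uw, k_uy, k_wy = _edge_key(u, w), _edge_key(u, y), _edge_key(w, y)
        if not (k_uw in edges and k_uy in edges and k_wy in edges):
            continue  # a shared edge was consumed by a heavier triangle
        med = median_distances(edges[k_uw], edges[k_uy], edges[k_wy])
        if min(med) <= 0:
            logger.warning(
                "skipping degenerate triangle %s: median edge lengths %s",
                tri.corners, med,
            )
            continue
        x = f"N{len(artificial) + 1}"
        artificial.append(x)
        provenance[x] = tri.corners
        del edges[k_uw], edges[k_uy], edges[k_wy]
        for corner, length in zip((u, w, y), med):
            edges[_edge_key(x, corner)] = float(length)
    return AugmentedNetwork(
        original_labels=network.labels,
        artificial_labels=tuple(artificial),
        edges=edges,
        provenance=provenance,
        delta=network.delta,
        threshold=float(threshold),
    )
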
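"""UltraNet: subdominant ultrametric and ultrametric network in O(n^2).

Given a complete positive dissimilarity W on n labelled points, the
*subdominant ultrametric* W* is the unique largest ultrametric dominated
by W; equivalently W*(u, v) is the minimax (least-resistance bottleneck)
path value between u and v in the weighted complete graph. The
*ultrametric network* G(V|W) keeps exactly the pairs where W already
equals W* -- which is the union of the edge sets of all minimum spanning
trees of W.

Both objects are computed simultaneously by a single Prim-style sweep:
a settled set grows one vertex at a time, always annexing the pending
vertex whose cheapest connection to the settled set is minimal. When
vertex u is annexed via parent p at cost kappa, the refined ultrametric
estimates are

    d(u, p) = kappa,    d(u, v) = max(kappa, d(p, v))  for settled v != p,

and values between already-settled vertices never change, which is what
brings the cost down from the O(n^3) Floyd-Warshall closure to O(n^2).
At every step d restricted to the settled set is exactly the subdominant
ultrametric of W restricted to that set.

An elementary-step counter is carried through the sweep so the quadratic
growth can be verified empirically without timing hardware.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io import LabeledDissimilarity

#: relative tolerance of the floating-point membership test W(u,v) == W*(u,v);
#: d-values are maxima of input weights, so exactly representable inputs
#: (integers in particular) are compared exactly.
MEMBERSHIP_RTOL = 1e-12


@dataclass(frozen=True)
class SubdominantUltrametric:
    """The largest ultrametric dominated by a dissimilarity W.

    ``values[i, j]`` is W*(labels[i], labels[j]): symmetric, zero diagonal,
    satisfying the strong triangle inequality
    W*(u, v) <= max(W*(u, w), W*(w, v)) and W* <= W entrywise.
    """

    labels: tuple[str, ...]
    values: np.ndarray

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown label {label!r}") from None

    def value(self, u: str, v: str) -> float:
        return float(self.values[self.index(u), self.index(v)])

    def is_ultrametric(self, rtol: float = MEMBERSHIP_RTOL) -> bool:
        """Strong triangle inequality check, vectorized over all triples."""
        m = self.values
        # ceiling[u,v] = min over w of max(m[u,w], m[v,w])
        ceiling = np.minimum.reduce(
            np.maximum(m[:, None, :], m[None, :, :]), axis=2
        )
        scale = np.maximum(np.abs(m), 1.0)
        return bool(np.all(m <= ceiling + rtol * scale))

    def dominated_by(self, D: LabeledDissimilarity, rtol: float = MEMBERSHIP_RTOL) -> bool:
        order = [D.index(l) for l in self.labels]
        w = D.matrix[np.ix_(order, order)]
        return bool(np.all(self.values <= w + rtol * np.maximum(np.abs(w), 1.0)))

    def as_dissimilarity(self) -> LabeledDissimilarity:
        """Reinterpret W* itself as the input dissimilarity (for idempotence)."""
        return LabeledDissimilarity(self.labels, self.values.copy())


@dataclass(frozen=True)
class UltrametricNetwork:
    """Vertex set plus the edges where W coincides with W* (within tolerance).

    ``edges`` maps sorted label pairs to the dissimilarity W of the pair.
    ``wstar`` additionally records W* per edge (always present; equal to the
    weight on exact edges, smaller on Delta-relaxed ones). ``delta`` is the
    relaxation tolerance used (0 for the exact network). ``step_count``
    carries the instrumented elementary-step counter of the run that built
    the network, when it was built by :func:`compute_ultranet`.
    """

    labels: tuple[str, ...]
    edges: dict[tuple[str, str], float]
    wstar: dict[tuple[str, str], float] = field(default_factory=dict)
    delta: float = 0.0
    step_count: int | None = None

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    def edge_set(self) -> frozenset:
        return frozenset(self.edges)

    def total_weight(self) -> float:
        return float(sum(self.edges.values()))

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {v: set() for v in self.labels}
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def is_connected(self) -> bool:
        if not self.labels:
            return False
        adj = self.adjacency()
        seen = {self.labels[0]}
        stack = [self.labels[0]]
        while stack:
            for w in adj[stack.pop()]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return len(seen) == len(self.labels)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.labels)
        for (u, v), w in self.edges.items():
            g.add_edge(u, v, weight=w)
        return g


@dataclass(frozen=True)
class AlgorithmState:
    """Snapshot of the sweep after an annexation (used for invariant checks).

    ``settled`` is the annexation order so far; ``key``/``prec`` give, for
    every pending vertex, its cheapest connection weight into the settled
    set and the settled vertex attaining it; ``d`` is the partially filled
    matrix of refined ultrametric estimates (+inf where undetermined).
    """

    settled: tuple[str, ...]
    pending: frozenset
    key: dict[str, float]
    prec: dict[str, str]
    d: np.ndarray
    labels: tuple[str, ...]


def _edge_key(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


def iterate_ultranet(D: LabeledDissimilarity, seed_label: str | None = None):
    """Run the sweep yielding an :class:`AlgorithmState` after each annexation.

    The generator exists for testing the loop invariants; use
    :func:`compute_ultranet` for results.
    """
    labels = D.labels
    n = D.n
    seed = labels[0] if seed_label is None else seed_label
    s = D.index(seed)
    W = D.matrix
    d = np.full((n, n), math.inf)
    np.fill_diagonal(d, 0.0)
    settled = [s]
    pending = set(range(n)) - {s}
    key = {u: W[s, u] for u in pending}
    prec = {u: s for u in pending}

    def snapshot():
        return AlgorithmState(
            settled=tuple(labels[i] for i in settled),
            pending=frozenset(labels[i] for i in pending),
            key={labels[u]: key[u] for u in pending},
            prec={labels[u]: labels[prec[u]] for u in pending},
            d=d.copy(),
            labels=labels,
        )

    yield snapshot()
    while pending:
        u = min(pending, key=lambda x: (key[x], labels[x]))
        kappa = key.pop(u)
        p = prec.pop(u)
        pending.remove(u)
        d[u, p] = d[p, u] = kappa
        for v in settled:
            if v != p:
                d[u, v] = d[v, u] = max(kappa, d[p, v])
        settled.append(u)
        for w in pending:
            if W[u, w] < key[w]:
                key[w] = W[u, w]
                prec[w] = u
        yield snapshot()


def compute_ultranet(
    D: LabeledDissimilarity,
    seed_label: str | None = None,
    rtol: float = MEMBERSHIP_RTOL,
) -> tuple[SubdominantUltrametric, UltrametricNetwork]:
    """Compute W* and the ultrametric network of ``D`` in O(n^2).

    Parameters
    ----------
    D
        Complete symmetric positive dissimilarity.
    seed_label
        Start vertex of the sweep; defaults to the first label. The result
        does not depend on this choice (any seed yields the same W* and the
        same network), it is fixed for determinism.
    rtol
        Relative tolerance of the edge membership test ``W(u,v) == W*(u,v)``.
        Exactly representable weights (integers) match exactly regardless.

    Returns
    -------
    (SubdominantUltrametric, UltrametricNetwork)
        The network's ``step_count`` attribute carries the instrumented
        elementary-step counter (Theta(n^2)).

    Notes
    -----
    Ties among equal-key pending vertices are broken toward the
    lexicographically smallest label; W* and the network are tie-invariant,
    so the choice has no observable effect beyond determinism.
    """
    labels = D.labels
    n = D.n
    if n < 2:
        raise ValidationError("need at least 2 vertices")
    seed = labels[0] if seed_label is None else seed_label
    s = D.index(seed)
    W = D.matrix
    d = np.full((n, n), math.inf)
    np.fill_diagonal(d, 0.0)

    settled = [s]
    pending = [u for u in range(n) if u != s]
    key = W[s].copy()
    prec = np.full(n, s, dtype=int)
    steps = n  # queue initialization

    for _ in range(n - 1):
        # extract-min with label tie-break (linear scan: O(n) per round)
        u = pending[0]
        for x in pending[1:]:
            steps += 1
            if key[x] < key[u] or (key[x] == key[u] and labels[x] < labels[u]):
                u = x
        pending.remove(u)
        kappa = key[u]
        p = prec[u]
        d[u, p] = d[p, u] = kappa
        dp = d[p]
        du = d[u]
        for v in settled:  # refine estimates toward the new vertex
            steps += 1
            if v != p:
                du[v] = d[v, u] = kappa if kappa >= dp[v] else dp[v]
        settled.append(u)
        Wu = W[u]
        for w in pending:  # decrease-key
            steps += 1
            if Wu[w] < key[w]:
                key[w] = Wu[w]
                prec[w] = u

    wstar = SubdominantUltrametric(labels, d)

    scale = np.maximum(np.abs(W), 1.0)
    member = np.abs(W - d) <= rtol * scale
    edges: dict[tuple[str, str], float] = {}
    wstar_map: dict[tuple[str, str], float] = {}
    iu, ju = np.triu_indices(n, k=1)
    for i, j in zip(iu, ju):
        if member[i, j]:
            k = _edge_key(labels[i], labels[j])
            edges[k] = float(W[i, j])
            wstar_map[k] = float(d[i, j])
    net = UltrametricNetwork(
        labels=labels, edges=edges, wstar=wstar_map, delta=0.0, step_count=steps
    )
    return wstar, net


def bottleneck_value(
    D: LabeledDissimilarity, Wstar: SubdominantUltrametric, u: str, v: str
) -> float:
    """W*(u, v): the minimum over all u-v paths of the maximum edge weight.

    The bottleneck B(P) of a path P is its heaviest edge; W*(u, v) is the
    least-resistance bottleneck, i.e. min over all paths of B(P). For u == v
    the value is 0 by the ultrametric axiom.
    """
    D.index(u), D.index(v)  # raises KeyError on unknown labels
    if u == v:
        return 0.0
    return Wstar.value(u, v)
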
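"""Reading and writing dissimilarity matrices, STR tables and networks.

Supported formats:

* square PHYLIP distance matrices (relaxed dialect: first line is the
  taxon count, labels are whitespace-delimited, not fixed-width),
* labelled CSV distance matrices (header row + index column),
* STR haplotype tables as CSV (rows = individuals, columns = loci),
* networks as GraphML, DOT or a deterministic tab-separated edge list.

Readers validate and repair their input: a distance matrix must be
square, its labels unique, its off-diagonal entries strictly positive,
and symmetric up to a relative tolerance of 1e-9 -- small asymmetries
(rounding noise in files) are repaired by averaging the two triangles,
larger ones are format errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: relative tolerance within which an asymmetric pair is repaired by averaging
ASYMMETRY_RTOL = 1e-9


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabeledDissimilarity:
    """A complete, symmetric, strictly positive dissimilarity on labelled points.

    Parameters
    ----------
    labels
        Ordered, unique vertex identifiers.
    matrix
        Symmetric ``(n, n)`` array of dissimilarities with zero diagonal and
        strictly positive off-diagonal entries.
    """

    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        n = len(labels)
        if n < 2:
            raise ValidationError("a dissimilarity needs at least 2 labels")
        if len(set(labels)) != n:
            raise ValidationError("duplicate labels in dissimilarity")
        if m.shape != (n, n):
            raise ValidationError(
                f"matrix shape {m.shape} does not match {n} labels"
            )
        if not np.array_equal(m, m.T):
            raise ValidationError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(m) != 0.0):
            raise ValidationError("diagonal entries must be zero")
        off = m[~np.eye(n, dtype=bool)]
        if np.any(off <= 0.0) or not np.all(np.isfinite(off)):
            i, j = _first_bad_offdiag(m)
            raise ValidationError(
                f"off-diagonal entry W({labels[i]},{labels[j]})={m[i, j]} "
                "must be finite and strictly positive"
            )

    @classmethod
    def from_pairs(
        cls, labels: Iterable[str], weights: Mapping[frozenset, float] | Mapping[tuple, float]
    ) -> "LabeledDissimilarity":
        """Build from an explicit map of unordered label pairs to weights."""
        labels = tuple(labels)
        index = {lab: i for i, lab in enumerate(labels)}
        m = np.zeros((len(labels), len(labels)))
        for pair, w in weights.items():
            u, v = tuple(pair)
            i, j = index[u], index[v]
            m[i, j] = m[j, i] = float(w)
        return cls(labels, m)

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown label {label!r}") from None

    def weight(self, u: str, v: str) -> float:
        """Dissimilarity between two distinct labels."""
        i, j = self.index(u), self.index(v)
        if i == j:
            raise ValidationError("self-pairs carry no weight")
        return float(self.matrix[i, j])

    def relabel(self, mapping: Mapping[str, str]) -> "LabeledDissimilarity":
        return LabeledDissimilarity(
            tuple(mapping.get(l, l) for l in self.labels), self.matrix.copy()
        )

    def permute(self, order: Iterable[int]) -> "LabeledDissimilarity":
        """Reorder vertices; the metric is unchanged."""
        order = list(order)
        return LabeledDissimilarity(
            tuple(self.labels[i] for i in order),
            self.matrix[np.ix_(order, order)].copy(),
        )


def _first_bad_offdiag(m: np.ndarray) -> tuple[int, int]:
    n = m.shape[0]
    for i in range(n):
        for j in range(n):
            if i != j and not (np.isfinite(m[i, j]) and m[i, j] > 0):
                return i, j
    return 0, 1


# ---------------------------------------------------------------------------
# Distance-matrix I/O
# ---------------------------------------------------------------------------

def _symmetrize(labels: list[str], m: np.ndarray) -> np.ndarray:
    """Average the two triangles; reject asymmetry beyond ASYMMETRY_RTOL."""
    scale = np.maximum(np.abs(m), np.abs(m.T))
    bad = np.abs(m - m.T) > ASYMMETRY_RTOL * np.where(scale > 0, scale, 1.0)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise FormatError(
            f"matrix is asymmetric beyond tolerance at pair "
            f"({labels[i]},{labels[j]}): {m[i, j]} vs {m[j, i]}"
        )
    return (m + m.T) / 2.0


def read_distance_matrix(path, format: str = "csv") -> LabeledDissimilarity:
    """Read a labelled square distance matrix.

    ``format`` is ``"phylip-square"`` (first line = taxon count, then one
    whitespace-delimited row per taxon starting with its label) or ``"csv"``
    (header row of labels, first column of labels). Asymmetries within a
    relative 1e-9 are repaired by averaging; anything larger is a
    :class:`~ultranet.errors.FormatError`.
    """
    path = Path(path)
    if format == "csv":
        df = pd.read_csv(path, index_col=0)
        labels = [str(x) for x in df.index]
        if [str(c) for c in df.columns] != labels:
            raise FormatError(
                f"{path}: row labels and column labels disagree"
            )
        m = df.to_numpy(dtype=float)
    elif format == "phylip-square":
        labels, m = _read_phylip(path)
    else:
        raise ValidationError(f"unknown distance-matrix format {format!r}")
    if len(labels) != len(set(labels)):
        raise ValidationError(f"{path}: duplicate labels")
    if m.shape[0] != m.shape[1]:
        raise FormatError(f"{path}: matrix is not square")
    m = _symmetrize(labels, m)
    np.fill_diagonal(m, 0.0)
    return LabeledDissimilarity(tuple(labels), m)


def _read_phylip(path: Path) -> tuple[list[str], np.ndarray]:
    with open(path) as fh:
        tokens = fh.read().split()
    if not tokens:
        raise FormatError(f"{path}: empty file")
    try:
        n = int(tokens[0])
    except ValueError:
        raise FormatError(f"{path}: first token must be the taxon count") from None
    expected = 1 + n * (n + 1)
    if len(tokens) != expected:
        raise FormatError(
            f"{path}: expected {expected} tokens for a square matrix of "
            f"{n} taxa, found {len(tokens)}"
        )
    labels, rows = [], []
    pos = 1
    for _ in range(n):
        labels.append(tokens[pos])
        row = tokens[pos + 1 : pos + 1 + n]
        try:
            rows.append([float(x) for x in row])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric entry in row {labels[-1]}: {exc}")
        pos += 1 + n
    return labels, np.array(rows, dtype=float)


def write_ultrametric(matrix, path, format: str = "csv") -> None:
    """Write a subdominant ultrametric as a square distance matrix.

    Values are written with 17 significant digits so that a round-trip
    through :func:`read_distance_matrix` is exact.
    """
    labels, values = matrix.labels, matrix.values
    if len(labels) < 2:
        raise ValidationError("at least 2 labels required")
    path = Path(path)
    if format == "csv":
        df = pd.DataFrame(values, index=list(labels), columns=list(labels))
        df.to_csv(path, float_format="%.17g")
    elif format == "phylip-square":
        with open(path, "w") as fh:
            fh.write(f"{len(labels)}\n")
            for lab, row in zip(labels, values):
                fh.write(lab + "\t" + "\t".join(f"{x:.17g}" for x in row) + "\n")
    else:
        raise ValidationError(f"unknown matrix format {format!r}")


# ---------------------------------------------------------------------------
# STR tables
# ---------------------------------------------------------------------------

def read_str_table(path):
    """Read a CSV STR haplotype table.

    Layout: header row of locus names, first column = individual identifier;
    an optional second column named ``population`` carries population tags.
    All remaining cells must be nonnegative integer repeat counts; missing
    cells are rejected.
    """
    from .strdist import STRTable  # local import to avoid a cycle

    path = Path(path)
    df = pd.read_csv(path, index_col=0, dtype=object)
    individuals = [str(x) for x in df.index]
    if len(individuals) != len(set(individuals)):
        raise ValidationError(f"{path}: duplicate individual identifiers")
    populations = None
    if len(df.columns) and str(df.columns[0]).lower() == "population":
        populations = tuple(str(x) for x in df.iloc[:, 0])
        df = df.iloc[:, 1:]
    loci = [str(c) for c in df.columns]
    if not loci:
        raise ValidationError(f"{path}: no locus columns")
    if df.isna().any().any():
        raise ValidationError(f"{path}: missing repeat counts are not allowed")
    counts = np.empty((len(individuals), len(loci)), dtype=int)
    for j, locus in enumerate(df.columns):
        for i, raw in enumerate(df[locus]):
            try:
                val = float(raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: non-integer repeat count {raw!r} at "
                    f"({individuals[i]}, {locus})"
                ) from None
            if val != int(val) or val < 0:
                raise ValidationError(
                    f"{path}: repeat count {raw!r} at ({individuals[i]}, {locus}) "
                    "must be a nonnegative integer"
                )
            counts[i, j] = int(val)
    return STRTable(
        individuals=tuple(individuals),
        loci=tuple(loci),
        counts=counts,
        populations=populations,
    )


def write_str_table(table, path) -> None:
    """Write an STR table back to CSV (inverse of :func:`read_str_table`)."""
    cols = {}
    if table.populations is not None:
        cols["population"] = list(table.populations)
    for j, locus in enumerate(table.loci):
        cols[locus] = table.counts[:, j]
    df = pd.DataFrame(cols, index=list(table.individuals))
    df.index.name = "id"
    df.to_csv(path)


# ---------------------------------------------------------------------------
# Network output
# ---------------------------------------------------------------------------

def _network_parts(network):
    """Normalize plain and augmented networks to (nodes, artificial, edges)."""
    artificial = frozenset(getattr(network, "artificial_labels", ()) or ())
    nodes = list(getattr(network, "all_labels", network.labels))
    edges = network.edges
    return nodes, artificial, edges


def _fmt(w: float) -> str:
    return f"{w:.12g}"


def write_network(network, path, format: str = "edge-tsv") -> None:
    """Write a network in GraphML, DOT or edge-tsv form.

    Every edge carries its dissimilarity as a numeric ``weight`` attribute
    (plus ``wstar`` where a relaxed network records the ultrametric value).
    Artificial vertices carry a boolean ``artificial`` attribute; their
    labels are generated as ``N1``, ``N2``, ... The ``edge-tsv`` dialect is
    one tab-separated ``label1 label2 weight`` line per edge with labels
    within a line and lines sorted lexicographically, so output is
    byte-reproducible.
    """
    nodes, artificial, edges = _network_parts(network)
    if not nodes:
        raise ValidationError("refusing to write an empty network")
    path = Path(path)
    if format == "edge-tsv":
        lines = sorted(
            "\t".join([*sorted((str(u), str(v))), _fmt(w)])
            for (u, v), w in edges.items()
        )
        path.write_text("".join(line + "\n" for line in lines))
    elif format == "graphml":
        import networkx as nx

        g = nx.Graph()
        for v in nodes:
            if artificial:
                g.add_node(v, artificial=bool(v in artificial))
            else:
                g.add_node(v)
        wstar = getattr(network, "wstar", None) or {}
        for (u, v), w in sorted(edges.items()):
            attrs = {"weight": float(w)}
            if (u, v) in wstar:
                attrs["wstar"] = float(wstar[(u, v)])
            g.add_edge(u, v, **attrs)
        nx.write_graphml(g, path)
    elif format == "dot":
        # written directly: the undirected DOT dialect is a few lines and the
        # networkx writers require pydot/pygraphviz
        out = ["graph ultranet {"]
        for v in sorted(nodes):
            attrs = ""
            if v in artificial:
                attrs = ' [artificial=true, shape=point]'
            out.append(f'  "{v}"{attrs};')
        for (u, v), w in sorted(edges.items()):
            out.append(f'  "{u}" -- "{v}" [weight={_fmt(w)}, label="{_fmt(w)}"];')
        out.append("}")
        path.write_text("\n".join(out) + "\n")
    else:
        raise ValidationError(f"unknown network format {format!r}")
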
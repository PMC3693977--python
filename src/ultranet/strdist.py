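"""Weighted dissimilarities from STR (microsatellite) haplotype profiles.

Y-chromosome STR haplotypes are vectors of per-locus repeat counts. Under
the single-step mutation model the natural dissimilarity between two
haplotypes is the weighted stepwise (L1) distance

    W(i, j) = sum over loci l of  w_l * |c(i, l) - c(j, l)|,

where the per-locus weights w_l reflect how informative each locus is.
Loci differ widely in mutation rate; the weighting scheme used here bins
the rates into terciles and assigns the three weights {1, 2, 4}. The
default orientation makes slowly mutating loci the heaviest (a repeat
difference at a stable locus signals deeper divergence than one at a
fast locus); the opposite orientation -- weight directly proportional to
rate -- is also supported, since both conventions exist in practice.

Identical haplotypes are merged into a single vertex (whose label
concatenates the individual ids) before the dissimilarity is built: the
network machinery requires strictly positive dissimilarities.

A deterministic fixture generator emulates multi-population Y-STR
samples: each population has its own locus-count centroid, individuals
scatter around it by small stepwise jitter, so networks built from the
fixture cluster by population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io import LabeledDissimilarity

#: the three tercile weights, slowest to fastest locus
TERCILE_WEIGHTS = (4.0, 2.0, 1.0)


@dataclass(frozen=True)
class STRTable:
    """Individuals x loci repeat counts, with per-locus weights.

    ``counts[i, j]`` is the repeat count of individual i at locus j;
    ``locus_weights`` defaults to all ones; ``populations`` optionally tags
    each individual with a population name.
    """

    individuals: tuple[str, ...]
    loci: tuple[str, ...]
    counts: np.ndarray
    locus_weights: np.ndarray | None = None
    populations: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if len(set(self.individuals)) != len(self.individuals):
            raise ValidationError("duplicate individual identifiers")
        if not self.loci:
            raise ValidationError("at least one locus column required")
        if counts.shape != (len(self.individuals), len(self.loci)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        if np.any(counts < 0):
            raise ValidationError("repeat counts must be nonnegative")
        if self.locus_weights is None:
            object.__setattr__(
                self, "locus_weights", np.ones(len(self.loci), dtype=float)
            )
        else:
            w = np.asarray(self.locus_weights, dtype=float)
            if w.shape != (len(self.loci),):
                raise ValidationError("one weight per locus required")
            if np.any(w <= 0):
                raise ValidationError("locus weights must be positive")
            object.__setattr__(self, "locus_weights", w)
        if self.populations is not None and len(self.populations) != len(
            self.individuals
        ):
            raise ValidationError("one population tag per individual required")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def with_weights(self, weights: Sequence[float]) -> "STRTable":
        return STRTable(
            self.individuals, self.loci, self.counts,
            np.asarray(weights, dtype=float), self.populations,
        )


def default_weights(
    mutation_rates: Sequence[float], orientation: str = "slow-heavy"
) -> np.ndarray:
    """Tercile weights {1, 2, 4} from per-locus mutation rates.

    Rates are ranked and split into terciles; with the default
    ``slow-heavy`` orientation the slowest tercile gets weight 4, the middle
    2 and the fastest 1 (``fast-heavy`` reverses this). Tied rates share the
    rank of their first occurrence, so equal rates always land in the same
    bin -- in particular, all-equal rates give every locus the extreme
    weight of its orientation.
    """
    rates = np.asarray(mutation_rates, dtype=float)
    if rates.ndim != 1 or rates.size == 0:
        raise ValidationError("mutation_rates must be a nonempty 1-d sequence")
    if np.any(rates <= 0):
        raise ValidationError("mutation rates must be positive")
    if orientation not in ("slow-heavy", "fast-heavy"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    n = rates.size
    # min-rank: number of strictly smaller rates
    minrank = np.array([np.sum(rates < r) for r in rates])
    bins = np.minimum((minrank * 3) // n, 2)  # 0 = slowest tercile
    table = TERCILE_WEIGHTS if orientation == "slow-heavy" else TERCILE_WEIGHTS[::-1]
    return np.array([table[b] for b in bins], dtype=float)


def build_dissimilarity(table: STRTable) -> LabeledDissimilarity:
    """Weighted stepwise (L1) dissimilarity between haplotype profiles.

    Individuals with identical profiles are merged into one vertex whose
    label joins their ids with ``+`` (in input order), keeping the
    dissimilarity strictly positive as the network construction requires.
    """
    profiles: dict[tuple, list[str]] = {}
    for ind, row in zip(table.individuals, table.counts):
        profiles.setdefault(tuple(row), []).append(ind)
    if len(profiles) < 2:
        raise ValidationError(
            "all individuals share one haplotype: no pairs to relate"
        )
    labels = tuple("+".join(ids) for ids in profiles.values())
    reps = np.array(list(profiles.keys()), dtype=float)
    w = table.locus_weights
    diff = np.abs(reps[:, None, :] - reps[None, :, :])
    matrix = np.tensordot(diff, w, axes=([2], [0]))
    np.fill_diagonal(matrix, 0.0)
    return LabeledDissimilarity(labels, matrix)


def generate_fixture(
    n_individuals: int,
    n_loci: int,
    n_populations: int,
    seed: int,
) -> STRTable:
    """Deterministic synthetic multi-population Y-STR sample.

    Each population draws an integer centroid per locus (repeat counts in
    the typical microsatellite range 10-25); individuals are assigned to
    populations round-robin and scatter around their centroid by stepwise
    jitter of at most one repeat per locus. Haplotypes are guaranteed
    distinct (duplicates are re-jittered deterministically). Per-locus
    mutation rates are drawn log-uniformly over 5e-4..1e-2 (the observed
    Y-STR range) and converted to tercile weights {1, 2, 4} with the
    slow-heavy orientation.

    Population structure dominates the jitter, so the resulting network
    clusters by population -- the qualitative behaviour of real
    multi-continental STR panels.
    """
    if min(n_individuals, n_loci, n_populations, 1 if seed is None else 1) < 1:
        raise ValidationError("all fixture parameters must be positive")
    if n_individuals < 2:
        raise ValidationError("need at least 2 individuals")
    rng = np.random.default_rng(seed)
    centroids = rng.integers(10, 26, size=(n_populations, n_loci))
    pop_of = np.arange(n_individuals) % n_populations
    counts = np.empty((n_individuals, n_loci), dtype=int)
    seen: set[tuple] = set()
    for i in range(n_individuals):
        base = centroids[pop_of[i]]
        for _ in range(1000):
            jitter = rng.integers(-1, 2, size=n_loci)
            row = np.maximum(base + jitter, 0)
            key = tuple(row)
            if key not in seen:
                break
        else:  # pragma: no cover - astronomically unlikely for sane shapes
            raise ValidationError(
                "could not generate distinct haplotypes; "
                "increase n_loci or decrease n_individuals"
            )
        seen.add(key)
        counts[i] = row
    rates = np.exp(rng.uniform(np.log(5e-4), np.log(1e-2), size=n_loci))
    weights = default_weights(rates)
    individuals = tuple(f"I{i + 1:03d}" for i in range(n_individuals))
    populations = tuple(f"P{p + 1:02d}" for p in pop_of)
    return STRTable(individuals, tuple(map(str, _locus_names(n_loci))), counts,
                    weights, populations)


def _locus_names(n_loci: int) -> list[str]:
    return [f"DYS{389 + i}" for i in range(n_loci)]
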
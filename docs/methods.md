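# Methods

## Model

The package works on a finite label set *V* with a complete, symmetric,
strictly positive dissimilarity *W*. Strict positivity is a modelling
requirement, not a convenience: a zero off-diagonal entry means two
"distinct" taxa are indistinguishable, and the subdominant-ultrametric
machinery assumes they have been identified first. The matrix readers
therefore reject zero off-diagonals, and the STR front end merges
identical haplotypes into one vertex (label = ids joined by `+`) before
building distances.

The subdominant ultrametric *W\** is the largest ultrametric dominated by
*W*; it coincides with the pairwise minimax (bottleneck) path value of
the weighted complete graph. The ultrametric network keeps the pairs
with *W = W\**, which is exactly the union of all MST edge sets; in
particular it is connected and contains between *n−1* and *n(n−1)/2*
edges.

## The sweep and its invariants

`compute_ultranet` grows a settled set from a seed vertex, always
annexing the pending vertex with the cheapest connection (Prim's
selection rule). Annexing *u* via parent *p* at cost κ sets
*d(u,p) = κ* and *d(u,v) = max(κ, d(p,v))* for the other settled *v*;
settled pairs are never revisited, which is what yields O(n²) overall.
The justifying invariants — after every annexation, *d* restricted to
the settled set is the subdominant ultrametric of *W* restricted to that
set, and every pending key is the cheapest connection into the settled
set — are exposed through the `iterate_ultranet` generator and asserted
against the brute-force closure in the test suite. The update rule
itself is the standard single-linkage/Prim refinement; its correctness
is established empirically by exact agreement with the independent
Floyd–Warshall-style closure on hundreds of random instances, which is
the authoritative check rather than any derivation.

Deterministic choices:

* **Seed vertex**: the first label. Any seed gives the same *W\** and
  network (asserted over all seeds on small instances); fixing it makes
  runs reproducible.
* **Priority queue**: a linear scan of pending keys. On a complete graph
  the scan is already O(n) per round — the same asymptotics a Fibonacci
  heap would give, with smaller constants and no pointer structure.
* **Ties** among equal-key pending vertices go to the lexicographically
  smallest label. *W\** and the edge set are tie-invariant, so this only
  pins down the annexation order, never the result. Label-based (not
  index-based) tie-breaking also makes the output invariant under
  relabeling/reordering of the input.
* **Membership test** *W(u,v) = W\*(u,v)* uses relative tolerance 1e-12.
  Every *d* value is a maximum of input weights, so exactly representable
  inputs (integers in particular) compare exactly and the tolerance only
  matters for weights produced by lossy upstream arithmetic.

The sweep carries an elementary-step counter (queue scans, estimate
refinements, key updates). Fitting log counts against log n over
n = 50…400 gives a slope of ≈ 2.0, a hardware-independent confirmation
of the quadratic cost; the acceptance script recomputes it.

## Oracles

Three independent reference routes ship in `ultranet.oracle` (guarded by
size caps, exhaustive beyond them): the O(n³) minimax closure
(pivot-wise `M(u,v) ← min(M(u,v), max(M(u,w), M(w,v)))`), the all-MST
edge union by exhaustive enumeration of all n^(n−2) labelled spanning
trees via Prüfer sequences (n ≤ 9), and pairwise min-bottleneck by
enumeration of all simple paths (n ≤ 8). They live in the package rather
than the test suite so users can cross-validate on their own small
instances (`ultranet oracle`).

## Δ-relaxation

`delta_network` admits every pair with *W(u,v) ≤ W\*(u,v) + Δ*
(inclusive, absolute Δ in the units of *W*; the formula is additive so a
relative tolerance would be a different model). It is a pure O(n²)
postprocess on the already-computed *W\**. Each edge stores both *W* and
*W\** so renderers can display the deviation. Boundary note: pairs with
*W* exactly equal to *W\* + Δ* are members — on the canonical 4-point
example with Δ = 2 both a–c (4 ≤ 2+2) and a–d (5 ≤ 3+2) sit on this
boundary and both join.

## Artificial vertices

A triangle (u, w, y) whose perimeter strictly exceeds the threshold is
replaced by a star through a new vertex *x* with Gromov-product edge
lengths *d(x,u) = (d(u,w) + d(u,y) − d(w,y))/2* (and cyclically). This
is the unique assignment for which the two-edge path through *x*
realizes each original pairwise distance exactly, and the star's total
weight is half the perimeter, so augmentation never increases total
edge weight. Design choices where the construction is genuinely open:

* Candidates are ranked canonically — perimeter descending, ties by the
  sorted label triple — and processed in one pass; a triangle that lost
  an edge to a heavier neighbour is skipped. This makes the result
  independent of edge input order (asserted on shuffled inputs).
* Artificial vertices (named `N1`, `N2`, … in creation order) never seed
  new candidate triangles: a single neighbourhood pass from the input
  network, so the operation cannot cascade or loop.
* Degenerate triangles (a median edge of length ≤ 0, i.e. the triangle
  inequality holds with equality or fails) are skipped with a warning
  rather than merging vertices: the identity of input taxa is preserved.
* The threshold comparison is strict (`>`).

Augmentation operates on whichever network the caller supplies; the CLI
applies it after Δ-relaxation (exact → relax → augment).

## STR distances

No single canonical formula exists for weighted Y-STR distances; this
package uses the weighted stepwise model,
*W(i,j) = Σ_l w_l · |c(i,l) − c(j,l)|*, the natural L1 choice under
single-step mutation, and documents it as such. Per-locus weights come
from mutation-rate terciles mapped to {4, 2, 1}: by default the slowest
tercile is heaviest (a repeat difference at a stable locus indicates
deeper divergence), but because the opposite convention — weight
directly proportional to rate — also appears in practice, both
orientations are exposed (`--weight-orientation {slow-heavy,fast-heavy}`).
Tied rates share the rank of their first occurrence so equal rates always
land in the same bin; with all rates equal every locus gets the extreme
weight of its orientation (4 under slow-heavy).

## The synthetic panel generator

`generate_fixture` emulates a multi-population Y-STR sample: each
population draws an integer centroid per locus in the typical
microsatellite repeat range (10–25); individuals join populations
round-robin and scatter around their centroid by at most one repeat per
locus; per-locus mutation rates are drawn log-uniformly over
5e-4…1e-2 (the observed Y-STR range) and converted to tercile weights.
Haplotype rows are guaranteed distinct by deterministic re-jittering, so
a panel of n individuals always yields an n-vertex network. Default
pipeline shapes of 54×12 and 41×7 match the dimensions of typical
published multi-continental and Native-American panels.

What the generator does **not** emulate: homoplasy structure (back
mutations collapsing lineages), population admixture, locus-specific
stepwise variances, multi-copy or null alleles, or missing data. Tests
passing on these fixtures therefore demonstrate the pipeline's
correctness and its qualitative clustering behaviour (population
structure dominating jitter), not the topology any real panel would
produce.

## Numerical choices and problem sizes

* Matrix readers repair asymmetries up to a relative 1e-9 by averaging
  the two triangles (rounding noise in files); larger asymmetries are
  format errors naming the offending pair.
* Matrix writers use 17 significant digits, so read/write round-trips
  are exact for doubles; the `edge-tsv` network dialect is fully sorted
  so golden-file comparisons are byte-exact.
* Verification batches: 200 random instances with n ∈ [3, 40] (mixed
  integer and continuous weights, integers drawn small to force MST
  ties) for closure agreement and axiom checks; 100 instances with
  n ∈ [3, 7] for the all-MST union; step counts at n = 50–400 for the
  complexity fit. These sizes keep the exhaustive oracles exact while
  the whole suite runs in seconds.

## Limitations

* Only the network and *W\** are produced; minimum-bottleneck paths are
  not reconstructed, and vertices cannot be added or removed
  incrementally after a run.
* Optimal realizations in the tight span and optimal Steiner trees are
  out of scope (NP-hard in general); the median-vertex operation is a
  local, single-pass heuristic, not a Steiner optimizer.
* Only 3-point medians are inserted; larger cliques are handled
  triangle by triangle in canonical order.
* The Δ-relaxed network is a postprocess on the exact *W\**; subdominant
  Δ-ultrametrics (relaxing the ultrametric itself) are not implemented.
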
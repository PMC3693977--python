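"""Delta-relaxed ultrametric networks.

The exact network keeps only pairs with W(u,v) = W*(u,v). Relaxing by a
tolerance Delta >= 0 admits every pair whose dissimilarity deviates from
its ultrametric value by at most Delta:

    E_Delta = { {u, v} : W(u, v) <= W*(u, v) + Delta }.

Connectivity grows monotonically with Delta; at Delta = 0 the exact
network is recovered, at Delta >= max W - min W* the graph is complete.
On its member pairs the relaxed graph realizes the map min(W, W* + Delta).
The relaxation is a pure postprocess over all pairs, O(n^2).
"""

from __future__ import annotations

import numpy as np

from .core import (
    MEMBERSHIP_RTOL,
    SubdominantUltrametric,
    UltrametricNetwork,
    _edge_key,
)
from .errors import ValidationError
from .io import LabeledDissimilarity


def delta_network(
    D: LabeledDissimilarity,
    Wstar: SubdominantUltrametric,
    delta: float,
    rtol: float = MEMBERSHIP_RTOL,
) -> UltrametricNetwork:
    """Build the Delta-ultrametric network from W and its W*.

    Parameters
    ----------
    D
        The dissimilarity the network is built on.
    Wstar
        Its subdominant ultrametric (from :func:`~ultranet.core.compute_ultranet`
        or :func:`~ultranet.oracle.bottleneck_closure`).
    delta
        Absolute tolerance, in the same units as W. ``delta = 0`` reproduces
        the exact network.

    Each edge is annotated with both its W weight (``edges``) and its W*
    value (``wstar``), so renderers can display the deviation.
    """
    if delta < 0:
        raise ValidationError(f"delta must be nonnegative, got {delta}")
    if Wstar.labels != D.labels:
        order = [Wstar.index(l) for l in D.labels]
        values = Wstar.values[np.ix_(order, order)]
    else:
        values = Wstar.values
    W = D.matrix
    n = D.n
    labels = D.labels
    scale = np.maximum(np.abs(W), 1.0)
    member = W <= values + delta + rtol * scale
    edges: dict[tuple[str, str], float] = {}
    wstar_map: dict[tuple[str, str], float] = {}
    iu, ju = np.triu_indices(n, k=1)
    for i, j in zip(iu, ju):
        if member[i, j]:
            k = _edge_key(labels[i], labels[j])
            edges[k] = float(W[i, j])
            wstar_map[k] = float(values[i, j])
    return UltrametricNetwork(
        labels=labels, edges=edges, wstar=wstar_map, delta=float(delta)
    )
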
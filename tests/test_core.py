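import itertools

import numpy as np
import pytest

from ultranet import (
    ValidationError,
    bottleneck_closure,
    bottleneck_value,
    compute_ultranet,
    iterate_ultranet,
)
from ultranet.io import LabeledDissimilarity
from conftest import CANONICAL_WSTAR, random_dissimilarity


class TestComputeUltranet:
    def test_canonical_fixture_values_and_edges(self, canonical):
        wstar, net = compute_ultranet(canonical)
        for (u, v), expected in CANONICAL_WSTAR.items():
            assert wstar.value(u, v) == expected
        assert net.edge_set() == {("a", "b"), ("b", "c"), ("c", "d")}
        assert net.edges[("b", "c")] == 2.0

    def test_tied_msts_all_contribute_edges(self, triangle):
        wstar, net = compute_ultranet(triangle)
        off = wstar.values[~np.eye(3, dtype=bool)]
        assert np.all(off == 1.0)
        assert net.edge_set() == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_two_vertices(self):
        D = LabeledDissimilarity(("a", "b"), np.array([[0.0, 7.0], [7.0, 0.0]]))
        wstar, net = compute_ultranet(D)
        assert wstar.value("a", "b") == 7.0
        assert net.edge_set() == {("a", "b")}

    def test_single_vertex_rejected(self):
        with pytest.raises(ValidationError):
            LabeledDissimilarity(("a",), np.zeros((1, 1)))

    def test_network_structural_invariants(self):
        rng = np.random.default_rng(11)
        for n, integer in [(5, True), (9, False), (17, True), (23, False)]:
            D = random_dissimilarity(rng, n, integer=integer)
            wstar, net = compute_ultranet(D)
            assert net.is_connected()
            assert n - 1 <= net.edge_count <= n * (n - 1) // 2
            assert wstar.is_ultrametric()
            assert wstar.dominated_by(D)
            for (u, v), w in net.edges.items():
                assert w == D.weight(u, v) == wstar.value(u, v)

    def test_seed_independence(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            D = random_dissimilarity(rng, 6, integer=True)
            wstar0, net0 = compute_ultranet(D)
            for seed in D.labels[1:]:
                wstar, net = compute_ultranet(D, seed_label=seed)
                assert np.array_equal(wstar.values, wstar0.values)
                assert net.edge_set() == net0.edge_set()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(3, 9))
            D = random_dissimilarity(rng, n, integer=bool(rng.integers(2)))
            wstar, net = compute_ultranet(D)
            order = list(rng.permutation(n))
            Dp = D.permute(order)
            wstar_p, net_p = compute_ultranet(Dp)
            # same values on the same label pairs, same edge set
            for u, v in itertools.combinations(D.labels, 2):
                assert wstar_p.value(u, v) == wstar.value(u, v)
            assert net_p.edge_set() == net.edge_set()

    def test_idempotence_on_an_ultrametric(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            D = random_dissimilarity(rng, int(rng.integers(3, 10)), integer=True)
            wstar, _ = compute_ultranet(D)
            wstar2, net2 = compute_ultranet(wstar.as_dissimilarity())
            assert np.array_equal(wstar2.values, wstar.values)
            n = wstar.n
            assert net2.edge_count == n * (n - 1) // 2  # every pair is exact

    def test_maximality_any_upward_perturbation_breaks_axioms(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            n = int(rng.integers(3, 8))
            D = random_dissimilarity(rng, n, integer=True)
            wstar, _ = compute_ultranet(D)
            for i, j in itertools.combinations(range(n), 2):
                for eps in (0.5, 1e-6):
                    bumped = wstar.values.copy()
                    bumped[i, j] += eps
                    bumped[j, i] += eps
                    m = type(wstar)(wstar.labels, bumped)
                    assert not (
                        m.is_ultrametric(rtol=0.0) and m.dominated_by(D, rtol=0.0)
                    )

    def test_step_counter_scales_quadratically(self):
        rng = np.random.default_rng(41)
        sizes = [50, 100, 200]
        counts = []
        for n in sizes:
            _, net = compute_ultranet(random_dissimilarity(rng, n))
            counts.append(net.step_count)
        slope = np.polyfit(np.log(sizes), np.log(counts), 1)[0]
        assert 1.8 <= slope <= 2.2


class TestLoopInvariants:
    """The sweep's state invariants, checked after every annexation."""

    def test_settled_prefix_carries_its_own_subdominant_ultrametric(self):
        rng = np.random.default_rng(47)
        for _ in range(5):
            D = random_dissimilarity(rng, 7, integer=True)
            for state in iterate_ultranet(D):
                if len(state.settled) < 2:
                    continue
                idx = [D.index(l) for l in state.settled]
                sub = LabeledDissimilarity(state.settled, D.matrix[np.ix_(idx, idx)])
                expected = bottleneck_closure(sub).values
                got = state.d[np.ix_(idx, idx)]
                assert np.array_equal(got, expected)

    def test_frontier_keys_are_cheapest_connections(self):
        rng = np.random.default_rng(53)
        D = random_dissimilarity(rng, 8)
        for state in iterate_ultranet(D):
            for u in state.pending:
                best = min(D.weight(u, v) for v in state.settled)
                assert state.key[u] == best == D.weight(state.prec[u], u)

    def test_settled_values_never_change_after_annexation(self):
        rng = np.random.default_rng(59)
        D = random_dissimilarity(rng, 8, integer=True)
        prev = None
        for state in iterate_ultranet(D):
            idx = [D.index(l) for l in state.settled]
            if prev is not None:
                pidx = idx[: len(prev)]
                assert np.array_equal(
                    state.d[np.ix_(pidx, pidx)], prev
                )
            prev = state.d[np.ix_(idx, idx)].copy()


class TestBottleneckValue:
    def test_canonical_pair_is_path_bottleneck(self, canonical):
        wstar, _ = compute_ultranet(canonical)
        assert bottleneck_value(canonical, wstar, "a", "d") == 3.0

    def test_identical_endpoints_are_at_zero(self, canonical):
        wstar, _ = compute_ultranet(canonical)
        assert bottleneck_value(canonical, wstar, "b", "b") == 0.0

    def test_two_vertex_instance_returns_the_weight(self):
        D = LabeledDissimilarity(("a", "b"), np.array([[0.0, 7.0], [7.0, 0.0]]))
        wstar, _ = compute_ultranet(D)
        assert bottleneck_value(D, wstar, "a", "b") == 7.0

    def test_unknown_label_raises(self, canonical):
        wstar, _ = compute_ultranet(canonical)
        with pytest.raises(KeyError):
            bottleneck_value(canonical, wstar, "a", "zzz")
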
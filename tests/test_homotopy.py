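"""Strongest-link anchoring, module symmetry, and their chance nulls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from homonet.graph import Partition, modularity_q
from homonet.homotopy import (
    anchoring_count,
    homotopy_report,
    module_pairing,
    null_anchoring,
    null_colocation,
    strongest_link_per_node,
    symmetry_ratios,
)


def planted_homotopic_W(nodes, homotopic=0.9, other=0.2, seed=0):
    """Every homotopic edge strictly dominates all other incident edges."""
    n = nodes.n_nodes
    rng = np.random.default_rng(seed)
    W = rng.uniform(0.05, other, (n, n))
    W = np.triu(W, 1)
    W = W + W.T
    for i, j in nodes.pair_map:
        W[i, j] = W[j, i] = homotopic
    np.fill_diagonal(W, 0.0)
    return W


def partition_from_pairs(nodes, colocate):
    """Partition with the given pairs together and the rest split."""
    a = np.zeros(nodes.n_nodes, dtype=int)
    nxt = 0
    placed = {}
    for k, (i, j) in enumerate(nodes.pair_map):
        if k in colocate:
            a[i] = a[j] = nxt
            nxt += 1
        else:
            a[i] = nxt
            a[j] = nxt + 1
            nxt += 2
    for u in nodes.unpaired_indices:
        a[u] = nxt
        nxt += 1
    return Partition(assignment=a, q_value=0.0)


class TestStrongestLinks:
    def test_hand_worked_example(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.8
        W[0, 2] = W[2, 0] = 0.5
        W[1, 2] = W[2, 1] = 0.6
        links = strongest_link_per_node(W)
        assert links.partners.tolist() == [1, 0, 1]

    def test_single_edge_node(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.4
        W[1, 2] = W[2, 1] = 0.9
        links = strongest_link_per_node(W)
        assert links.partners[0] == 1  # node 0's only edge is selected
        assert not links.isolated.any()

    def test_tie_broken_to_lowest_index_and_flagged(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[0, 2] = W[2, 0] = 0.5
        links = strongest_link_per_node(W)
        assert links.partners[0] == 1
        assert links.tied[0]
        assert not links.tied[1]

    def test_isolated_node_flagged(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        with pytest.warns(RuntimeWarning, match="isolated"):
            links = strongest_link_per_node(W)
        assert links.partners[2] == -1
        assert links.isolated[2]

    @given(st.floats(0.1, 5.0), st.floats(0.0, 2.0))
    @settings(deadline=None, max_examples=30)
    def test_monotone_weight_transform_invariance(self, scale, shift):
        rng = np.random.default_rng(17)
        W = oracles.random_weight_matrix(rng, 8, density=1.0)
        t = np.where(W > 0, scale * W + shift * W**2, 0.0)  # strictly monotone
        a = strongest_link_per_node(W).partners
        b = strongest_link_per_node(t).partners
        np.testing.assert_array_equal(a, b)


class TestAnchoring:
    def test_planted_maximum_anchors_all_pairs(self, nodes28):
        W = planted_homotopic_W(nodes28)
        links = strongest_link_per_node(W)
        anchored, total = anchoring_count(links, nodes28)
        assert (anchored, total) == (24, 24)

    def test_no_homotopic_maximum_anchors_none(self, nodes28):
        W = planted_homotopic_W(nodes28)
        for i, j in nodes28.pair_map:  # demote every homotopic edge
            W[i, j] = W[j, i] = 0.01
        anchored, _ = anchoring_count(strongest_link_per_node(W), nodes28)
        assert anchored == 0

    def test_default_denominator_is_24(self, nodes28):
        _, total = anchoring_count(
            strongest_link_per_node(planted_homotopic_W(nodes28)), nodes28
        )
        assert total == 24


class TestModulePairing:
    def test_split_partition_colocates_none(self, nodes28):
        part = partition_from_pairs(nodes28, colocate=set())
        assert module_pairing(part, nodes28)[0] == 0

    def test_single_module_colocates_all(self, nodes28):
        part = Partition(assignment=np.zeros(28, dtype=int), q_value=0.0)
        assert module_pairing(part, nodes28)[0] == 12

    @pytest.mark.parametrize("seed", range(10))
    def test_random_partition_matches_brute_count(self, nodes8, seed):
        rng = np.random.default_rng(seed)
        raw = rng.integers(0, 3, 8)
        _, a = np.unique(raw, return_inverse=True)
        part = Partition(assignment=a, q_value=0.0)
        count, pairs = module_pairing(part, nodes8)
        brute = sum(1 for i, j in nodes8.pair_map if a[i] == a[j])
        assert count == brute
        assert all(a[i] == a[j] for i, j in pairs)


class TestSymmetryRatios:
    def test_single_module_totals(self, nodes28):
        part = Partition(assignment=np.zeros(28, dtype=int), q_value=0.0)
        _, (K, N) = symmetry_ratios(part, nodes28)
        assert (K, N) == (24, 28)

    def test_split_partition_totals(self, nodes28):
        part = partition_from_pairs(nodes28, colocate=set())
        _, (K, N) = symmetry_ratios(part, nodes28)
        assert (K, N) == (0, 28)

    def test_eight_colocated_pairs_give_sixteen(self, nodes28):
        part = partition_from_pairs(nodes28, colocate=set(range(8)))
        per_module, (K, N) = symmetry_ratios(part, nodes28)
        assert (K, N) == (16, 28)
        assert sum(k for k, _ in per_module) == K
        assert sum(n for _, n in per_module) == N

    @pytest.mark.parametrize("seed", range(10))
    def test_k_equals_twice_colocated_pairs(self, nodes28, seed):
        rng = np.random.default_rng(seed)
        raw = rng.integers(0, 5, 28)
        _, a = np.unique(raw, return_inverse=True)
        part = Partition(assignment=a, q_value=0.0)
        _, (K, _) = symmetry_ratios(part, nodes28)
        assert K == 2 * module_pairing(part, nodes28)[0]


class TestNullAnchoring:
    def test_observed_zero_gives_p_one(self, nodes4):
        assert null_anchoring(nodes4, 0, n_perm=199, seed=0).p_value == 1.0
        assert null_anchoring(nodes4, 0, mode="exact").p_value == 1.0

    def test_exact_matches_edge_order_enumeration(self, nodes4):
        """The subset recursion reproduces the literal 6!-ordering law."""
        res = null_anchoring(nodes4, 2, mode="exact")
        brute = oracles.anchoring_pmf_enumeration(4, {0: 1, 1: 0, 2: 3, 3: 2})
        for k, p in brute.items():
            assert res.null_pmf[k] == pytest.approx(p, abs=1e-12)
        # marginal anchor probability per node is 1/(n-1) = 1/3
        mean = sum(k * p for k, p in res.null_pmf.items())
        assert mean == pytest.approx(4 / 3, abs=1e-12)

    def test_exact_matches_monte_carlo_at_n8(self, nodes8):
        exact = null_anchoring(nodes8, 3, mode="exact")
        mc = null_anchoring(nodes8, 3, n_perm=20000, seed=1, mode="permute")
        p = exact.p_value
        se = np.sqrt(p * (1 - p) / 20000)
        assert abs(mc.p_value - p) < 3 * se + 1e-4

    def test_planted_network_minimal_p(self, nodes28):
        res = null_anchoring(nodes28, 24, n_perm=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_exact_too_large(self, nodes28):
        with pytest.raises(ValueError, match="<= 10"):
            null_anchoring(nodes28, 5, mode="exact")

    def test_permutation_p_super_uniform_under_null(self, nodes28):
        """Data drawn from the null itself: empirical type-I error at the
        0.05 level stays near or below nominal (200 replicates,
        n_perm = 199)."""
        rng = np.random.default_rng(2024)
        rejections = 0
        for _ in range(200):
            U = rng.random((28, 28))
            W = np.triu(U, 1)
            W = W + W.T
            anchored, _ = anchoring_count(strongest_link_per_node(W), nodes28)
            p = null_anchoring(
                nodes28, anchored, n_perm=199, seed=int(rng.integers(2**31))
            ).p_value
            rejections += p <= 0.05
        assert rejections / 200 <= 0.07


class TestNullColocation:
    def test_single_module_degenerate(self, nodes28):
        res = null_colocation([28], nodes28, observed=12, n_perm=199, seed=0)
        assert res.p_value == 1.0

    def test_two_pair_exact_distribution(self, nodes4):
        res = null_colocation([2, 2], nodes4, observed=2, mode="exact")
        assert res.null_pmf == pytest.approx({0: 2 / 3, 2: 1 / 3})
        assert res.p_value == pytest.approx(1 / 3)

    def test_exact_matches_permutation_enumeration(self, nodes8):
        res = null_colocation([4, 4], nodes8, observed=1, mode="exact")
        brute = oracles.colocation_pmf_enumeration([4, 4], nodes8.pair_map)
        for k, p in brute.items():
            assert res.null_pmf[k] == pytest.approx(p, abs=1e-12)

    def test_size_mismatch_rejected(self, nodes28):
        with pytest.raises(ValueError, match="sum"):
            null_colocation([10, 10], nodes28, observed=0)

    def test_planted_symmetric_partition_low_p(self, nodes28):
        res = null_colocation(
            [7, 7, 7, 7], nodes28, observed=12, n_perm=999, seed=3
        )
        assert res.p_value <= 0.01


class TestReport:
    def test_planted_network_report(self, nodes28):
        W = planted_homotopic_W(nodes28)
        part = partition_from_pairs(nodes28, colocate=set(range(12)))
        part = Partition(part.assignment, modularity_q(W, part.assignment))
        rep = homotopy_report(W, part, nodes28, n_perm=199, seed=0)
        assert rep.anchored_nodes == 24
        assert rep.pairs_colocated == 12
        assert rep.symmetry_total == (24, 28)
        assert rep.p_anchoring <= 0.005
        assert rep.flags["n_unique_homotopic_strongest_links"] == 12
        # each pair's selections collapse onto the 12 homotopic links
        assert rep.flags["n_unique_strongest_links"] >= 12
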
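"""Weighted correlation, Fisher transform, group edge tests, FDR,
network construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import oracles
from homonet.connectivity import (
    DegenerateSeriesError,
    SubjectConnectivity,
    build_group_network,
    fdr_bh,
    fisher_z,
    group_edge_test,
    subject_connectivity,
    weighted_correlation,
)
from homonet.design import condition_regressor
from homonet.synthetic import CouplingModel, simulate_group


class TestWeightedCorrelation:
    def test_self_correlation_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        w = np.array([1.0, 2.0, 0.5, 1.0])
        assert weighted_correlation(x, x, w) == pytest.approx(1.0)

    def test_constant_weights_reduce_to_pearson(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 40))
        w = np.full(40, 0.37)
        assert weighted_correlation(x, y, w) == pytest.approx(
            np.corrcoef(x, y)[0, 1], abs=1e-12
        )

    def test_perfect_linear_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert weighted_correlation(x, 2 * x, np.ones(4)) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_direct_moment_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 25))
        w = rng.uniform(0, 1, 25)
        w[rng.random(25) < 0.3] = 0.0
        if np.count_nonzero(w) < 3:
            w[:3] = 1.0
        assert weighted_correlation(x, y, w) == pytest.approx(
            oracles.weighted_pearson_direct(x, y, w), abs=1e-10
        )

    def test_zero_weight_scans_are_ignored(self):
        x = np.array([1.0, 2.0, 3.0, 99.0])
        y = np.array([1.0, 3.0, 2.0, -50.0])
        w = np.array([1.0, 1.0, 1.0, 0.0])
        assert weighted_correlation(x, y, w) == pytest.approx(
            np.corrcoef(x[:3], y[:3])[0, 1]
        )

    def test_degenerate_variance(self):
        with pytest.raises(DegenerateSeriesError):
            weighted_correlation(
                np.ones(5), np.arange(5.0), np.ones(5)
            )

    def test_too_few_weighted_scans(self):
        with pytest.raises(ValueError, match="3 scans"):
            weighted_correlation(
                np.arange(5.0), np.arange(5.0), np.array([1.0, 1, 0, 0, 0])
            )


class TestFisherZ:
    def test_known_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)
        assert fisher_z(-0.5) == pytest.approx(-0.5493, abs=1e-4)

    def test_out_of_domain(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)
        assert np.isfinite(fisher_z(1.0, clip=True))

    @given(st.floats(-5, 5))
    @settings(deadline=None, max_examples=50)
    def test_tanh_round_trip(self, z):
        # atanh(tanh(z)) loses float precision as |tanh| saturates toward 1,
        # so the identity is checked on the range where r is representable
        assert fisher_z(np.tanh(z)) == pytest.approx(z, abs=1e-12, rel=1e-12)


class TestSubjectConnectivity:
    def test_equals_pairwise_weighted_correlation(self):
        rng = np.random.default_rng(5)
        ts = rng.standard_normal((5, 60))
        w = rng.uniform(0.1, 1, 60)
        sc = subject_connectivity(ts, w)
        for i in range(5):
            for j in range(i + 1, 5):
                expect = np.arctanh(weighted_correlation(ts[i], ts[j], w))
                assert sc.z[i, j] == pytest.approx(expect, abs=1e-10)
        np.testing.assert_array_equal(np.diag(sc.z), 0.0)

    def test_identical_series_hit_clip_boundary(self):
        ts = np.vstack([np.arange(10.0), np.arange(10.0)])
        sc = subject_connectivity(ts, np.ones(10))
        assert np.isfinite(sc.z[0, 1])
        assert sc.z[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_null_z_spread_matches_sampling_theory(self):
        """Independent noise at ~194 scans: |z| stays within ~2.5 null SDs
        (1/sqrt(n-3)) for all pairs in >= 95% of seeds."""
        rng_ok = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            ts = rng.standard_normal((8, 194))
            sc = subject_connectivity(ts, np.ones(194))
            if np.abs(sc.z[np.triu_indices(8, 1)]).max() < 0.35:
                rng_ok += 1
        assert rng_ok >= 38

    def test_planted_correlation_recovered(self, nodes28, paradigm):
        """Pairs planted at r = 0.6: cohort-mean Fisher score lands within
        0.1 of atanh(0.6) ~= 0.693."""
        m = CouplingModel(0.6, 0.3, 0.1, task_gain=0, drift_amp=0, motion_coupling=0)
        subs = simulate_group(nodes28, m, paradigm, n_subjects=18, seed=9)
        zbar = np.zeros((28, 28))
        for s in subs:
            zbar += subject_connectivity(s.data, np.ones(s.n_scans)).z
        zbar /= len(subs)
        homo_mean = np.mean([zbar[i, j] for i, j in nodes28.pair_map])
        assert homo_mean == pytest.approx(np.arctanh(0.6), abs=0.1)


class TestGroupEdgeTest:
    def test_all_zero_edge(self):
        subs = [
            SubjectConnectivity(np.zeros((3, 3)), "c", f"s{i}") for i in range(5)
        ]
        mean_z, t, p = group_edge_test(subs)
        assert t[0, 1] == 0.0
        assert p[0, 1] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reference_t(self, seed):
        rng = np.random.default_rng(seed)
        zs = rng.standard_normal((10, 4, 4)) * 0.3 + 0.2
        zs = (zs + zs.transpose(0, 2, 1)) / 2
        for z in zs:
            np.fill_diagonal(z, 0)
        subs = [SubjectConnectivity(z, "c", f"s{i}") for i, z in enumerate(zs)]
        mean_z, t, p = group_edge_test(subs)
        ref = stats.ttest_1samp(zs[:, 0, 1], 0.0)
        assert t[0, 1] == pytest.approx(ref.statistic, abs=1e-10)
        assert p[0, 1] == pytest.approx(ref.pvalue, abs=1e-10)
        # textbook formula m / (s / sqrt(n))
        m, s = zs[:, 0, 1].mean(), zs[:, 0, 1].std(ddof=1)
        assert t[0, 1] == pytest.approx(m / (s / np.sqrt(10)), abs=1e-10)

    def test_too_few_subjects(self):
        subs = [SubjectConnectivity(np.zeros((3, 3)), "c", f"s{i}") for i in range(2)]
        with pytest.raises(ValueError, match="3 subjects"):
            group_edge_test(subs)

    def test_zero_variance_nonzero_mean_convention(self):
        z = np.zeros((3, 3))
        z[0, 1] = z[1, 0] = 0.4
        subs = [SubjectConnectivity(z.copy(), "c", f"s{i}") for i in range(4)]
        with pytest.warns(RuntimeWarning, match="zero across-subject variance"):
            _, t, p = group_edge_test(subs)
        assert p[0, 1] == 0.0


class TestFdrBh:
    def test_hand_worked_stepup(self):
        mask = fdr_bh(np.array([0.01, 0.02, 0.03, 0.5]), q=0.05)
        assert mask.tolist() == [True, True, True, False]

    def test_degenerate_inputs(self):
        assert fdr_bh(np.ones(6)).sum() == 0
        assert fdr_bh(np.zeros(6)).sum() == 6
        assert fdr_bh(np.array([])).size == 0

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_stepup(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 11))
        p = rng.uniform(0, 1, n)
        if seed % 3 == 0:
            p = np.round(p, 1)  # exercise ties
        q = float(rng.choice([0.01, 0.05, 0.1, 0.2]))
        np.testing.assert_array_equal(fdr_bh(p, q), oracles.bh_stepup(p, q))


class TestBuildGroupNetwork:
    def _cohort(self, nodes, paradigm, model, seed, n=18):
        subs = simulate_group(nodes, model, paradigm, n_subjects=n, seed=seed)
        w = condition_regressor(paradigm, "right").weights
        return [
            subject_connectivity(s.data, w, "right", s.subject_id) for s in subs
        ]

    def test_planted_homotopic_edges_all_present(self, nodes28, paradigm):
        conns = self._cohort(
            nodes28, paradigm, CouplingModel(0.6, 0.3, 0.1), seed=7
        )
        net = build_group_network(conns, q=0.05)
        for i, j in nodes28.pair_map:
            assert net.W[i, j] > 0

    def test_weights_are_back_transformed_means(self, nodes28, paradigm):
        conns = self._cohort(nodes28, paradigm, CouplingModel(0.6, 0.3, 0.1), seed=7)
        net = build_group_network(conns, q=0.05)
        present = net.W > 0
        np.testing.assert_allclose(
            net.W[present], np.tanh(net.mean_z[present]), atol=1e-12
        )
        assert net.W.max() < 1.0
        net_z = build_group_network(conns, q=0.05, weight_convention="mean-z")
        np.testing.assert_allclose(
            net_z.W[net_z.W > 0], net_z.mean_z[net_z.W > 0], atol=1e-12
        )

    def test_no_signal_model_controls_false_edges(self, nodes28, paradigm):
        """Pure-noise cohorts: FDR keeps the average discovered-edge
        fraction at or below the nominal level."""
        m = CouplingModel(0, 0, 0, task_gain=0, drift_amp=0, motion_coupling=0)
        fracs = []
        for seed in range(20):
            conns = self._cohort(nodes28, paradigm, m, seed=seed, n=10)
            net = build_group_network(conns, q=0.05)
            fracs.append(net.n_edges / 378)
        assert np.mean(fracs) <= 0.05

    def test_degenerate_q_gives_empty_network(self, nodes28, paradigm):
        conns = self._cohort(nodes28, paradigm, CouplingModel(0.6, 0.3, 0.1), seed=7)
        net = build_group_network(conns, q=0.0)
        assert net.n_edges == 0

    def test_edge_count_bounded(self, nodes28, paradigm):
        conns = self._cohort(nodes28, paradigm, CouplingModel(0.6, 0.3, 0.1), seed=7)
        net = build_group_network(conns, q=0.05)
        assert net.n_edges <= 378
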
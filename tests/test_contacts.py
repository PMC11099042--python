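"""Matrix balancing, compartments, APA and SCC."""

import numpy as np
import pytest

from chromdyn.contacts import (
    ContactMatrix,
    MatrixError,
    apa,
    compartment_eigenvector,
    compartment_switch,
    expected_by_distance,
    kr_balance,
    oe_matrix,
    scc,
    CompartmentTrack,
)
from chromdyn.intervals import GenomicInterval
from chromdyn.simulate import SimConfig, simulate_loops_and_matrix


def random_symmetric(rng, n, offset=0.1):
    A = rng.random((n, n))
    return A + A.T + offset


def two_block_matrix(n=60, high=10.0, low=1.0):
    counts = np.full((n, n), low)
    half = n // 2
    counts[:half, :half] = high
    counts[half:, half:] = high
    return ContactMatrix("chr1", 100_000, counts, np.ones(n, bool))


class TestContactMatrix:
    def test_rejects_asymmetric(self):
        with pytest.raises(MatrixError):
            ContactMatrix("chr1", 10_000, np.array([[1.0, 2.0], [3.0, 1.0]]))

    def test_zero_marginal_bins_masked_by_default(self):
        counts = np.diag([0.0, 4.0, 5.0])
        m = ContactMatrix("chr1", 10_000, counts)
        assert m.mask.tolist() == [False, True, True]


class TestKrBalance:
    def test_doubly_stochastic_is_fixed_point(self):
        counts = np.array([[0.5, 0.5], [0.5, 0.5]])
        m = ContactMatrix("chr1", 1_000, counts, np.ones(2, bool))
        balanced, bias, info = kr_balance(m)
        np.testing.assert_allclose(bias, 1.0, atol=1e-6)
        np.testing.assert_allclose(balanced.counts, counts, atol=1e-6)

    def test_two_by_two_hand_check(self):
        counts = np.array([[2.0, 1.0], [1.0, 2.0]])
        m = ContactMatrix("chr1", 1_000, counts, np.ones(2, bool))
        balanced, bias, _ = kr_balance(m)
        # symmetric system: b = 1/sqrt(3), balanced = counts / 3
        np.testing.assert_allclose(bias, 1 / np.sqrt(3), rtol=1e-6)
        np.testing.assert_allclose(balanced.counts.sum(axis=1), 1.0, rtol=1e-8)

    def test_row_sums_equal_on_random_200x200(self, rng):
        m = ContactMatrix("chr1", 10_000, random_symmetric(rng, 200),
                          np.ones(200, bool))
        balanced, bias, info = kr_balance(m)
        assert info["max_rel_rowsum_dev"] < 1e-6
        # bias factors reproduce the balanced matrix entrywise
        np.testing.assert_allclose(
            balanced.counts, m.counts * np.outer(bias, bias), rtol=1e-10
        )

    def test_invariant_to_symmetric_permutation(self, rng):
        n = 50
        m = ContactMatrix("chr1", 10_000, random_symmetric(rng, n), np.ones(n, bool))
        perm = rng.permutation(n)
        mp = ContactMatrix("chr1", 10_000, m.counts[np.ix_(perm, perm)],
                           np.ones(n, bool))
        b1 = kr_balance(m)[0].counts
        b2 = kr_balance(mp)[0].counts
        np.testing.assert_allclose(b2, b1[np.ix_(perm, perm)], rtol=1e-6)

    def test_masked_bins_stay_zero(self, rng):
        n = 40
        mask = np.ones(n, bool)
        mask[[3, 17]] = False
        m = ContactMatrix("chr1", 10_000, random_symmetric(rng, n), mask)
        balanced, bias, _ = kr_balance(m)
        assert np.isnan(bias[3]) and np.isnan(bias[17])
        assert (balanced.counts[3] == 0).all()

    def test_all_masked_is_an_error(self):
        m = ContactMatrix("chr1", 1_000, np.zeros((3, 3)), np.zeros(3, bool))
        with pytest.raises(MatrixError):
            kr_balance(m)


class TestCompartments:
    def test_two_block_split_is_exact(self):
        m = two_block_matrix()
        track = np.concatenate([np.ones(30), -np.ones(30)])
        comp = compartment_eigenvector(m, track)
        assert (comp.labels[:30] == "A").all()
        assert (comp.labels[30:] == "B").all()

    def test_orientation_track_negation_flips_labels(self):
        m = two_block_matrix()
        track = np.concatenate([np.ones(30), -np.ones(30)])
        a = compartment_eigenvector(m, track)
        b = compartment_eigenvector(m, -track)
        assert ((a.labels == "A") == (b.labels == "B")).all()

    def test_invariant_to_positive_scaling(self):
        m = two_block_matrix()
        track = np.concatenate([np.ones(30), -np.ones(30)])
        a = compartment_eigenvector(m, track)
        b = compartment_eigenvector(m.scaled(7.3), track)
        assert (a.labels == b.labels).all()

    def test_constant_matrix_is_degenerate(self):
        m = ContactMatrix("chr1", 100_000, np.ones((30, 30)), np.ones(30, bool))
        with pytest.raises(MatrixError):
            compartment_eigenvector(m)

    def test_simulated_recovery_with_planted_signs(self):
        cfg = SimConfig(seed=5, n_loops=50, loop_enrichment=1.0)
        sim = simulate_loops_and_matrix(cfg)
        comp = compartment_eigenvector(sim.matrix_a, sim.compartment_signs_a)
        agree = np.mean((comp.eigenvector > 0) == (sim.compartment_signs_a > 0))
        assert agree >= 0.95


class TestCompartmentSwitch:
    def _track(self, values):
        v = np.asarray(values, float)
        labels = np.where(v > 0, "A", "B").astype(object)
        return CompartmentTrack("chr1", 100_000, v, labels)

    def test_identical_tracks_have_zero_switch(self):
        t = self._track([1, -1, 1, -1])
        res = compartment_switch(t, t)
        assert res["pct_A_to_B"] == 0 and res["pct_B_to_A"] == 0

    def test_full_flip_sums_to_100(self):
        a = self._track([1, -1, 1, -1])
        b = self._track([-1, 1, -1, 1])
        res = compartment_switch(a, b)
        assert res["pct_A_to_B"] + res["pct_B_to_A"] == 100.0

    def test_planted_switch_fraction_recovered_exactly(self):
        cfg = SimConfig(seed=9, n_loops=50)
        sim = simulate_loops_and_matrix(cfg)
        a = self._track(sim.compartment_signs_a)
        b = self._track(sim.compartment_signs_b)
        res = compartment_switch(a, b)
        n_flipped = (sim.compartment_signs_a != sim.compartment_signs_b).sum()
        total_pct = res["pct_A_to_B"] + res["pct_B_to_A"]
        assert total_pct == pytest.approx(100 * n_flipped / cfg.n_bins)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(MatrixError):
            compartment_switch(self._track([1, -1]), self._track([1, -1, 1]))


class TestApa:
    def _loop(self, i, j, res=10_000):
        return (
            GenomicInterval("chr1", i * res, (i + 1) * res),
            GenomicInterval("chr1", j * res, (j + 1) * res),
        )

    def test_uniform_matrix_scores_one(self):
        m = ContactMatrix("chr1", 10_000, np.ones((100, 100)), np.ones(100, bool))
        res = apa(m, [self._loop(30, 70)], w=10, norm="observed")
        assert res.apa_score == pytest.approx(1.0)
        assert (res.aggregate == 1.0).all()

    def test_planted_3x_pixel_recovered(self):
        counts = np.ones((100, 100))
        counts[40, 70] = counts[70, 40] = 3.0
        m = ContactMatrix("chr1", 10_000, counts, np.ones(100, bool))
        res = apa(m, [self._loop(40, 70)], w=10, norm="observed")
        assert res.apa_score == pytest.approx(3.0)

    def test_near_diagonal_and_edge_loops_skipped(self):
        m = ContactMatrix("chr1", 10_000, np.ones((100, 100)), np.ones(100, bool))
        res = apa(m, [self._loop(30, 40), self._loop(2, 60), self._loop(30, 70)],
                  w=10)
        assert res.n_loops_used == 1
        assert res.n_loops_skipped == 2

    def test_no_usable_loops_is_an_error(self):
        m = ContactMatrix("chr1", 10_000, np.ones((100, 100)), np.ones(100, bool))
        with pytest.raises(MatrixError):
            apa(m, [self._loop(30, 40)], w=10)


class TestScc:
    def test_self_similarity_is_one(self, rng):
        counts = random_symmetric(rng, 80)
        m = ContactMatrix("chr1", 100_000, counts, np.ones(80, bool))
        assert scc(m, m) == pytest.approx(1.0)

    def test_independent_noise_is_near_zero(self, rng):
        a = ContactMatrix("chr1", 100_000, random_symmetric(rng, 120),
                          np.ones(120, bool))
        b = ContactMatrix("chr1", 100_000, random_symmetric(rng, 120),
                          np.ones(120, bool))
        assert abs(scc(a, b, h=0)) < 0.1

    def test_replicates_more_similar_than_cross_condition(self):
        sim1 = simulate_loops_and_matrix(SimConfig(seed=21, n_loops=50,
                                                   loop_enrichment=1.0))
        sim2 = simulate_loops_and_matrix(SimConfig(seed=22, n_loops=50,
                                                   loop_enrichment=1.0))
        # same planted structure, independent noise = replicates
        rep = scc(sim1.matrix_a, sim2.matrix_a)
        cross = scc(sim1.matrix_a, sim1.matrix_b)
        assert rep > cross

    def test_shape_mismatch_rejected(self, rng):
        a = ContactMatrix("chr1", 100_000, random_symmetric(rng, 10), np.ones(10, bool))
        b = ContactMatrix("chr1", 50_000, random_symmetric(rng, 10), np.ones(10, bool))
        with pytest.raises(MatrixError):
            scc(a, b)


class TestOeMatrix:
    def test_expected_by_distance_on_toeplitz(self):
        n = 20
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        counts = 100.0 / (1.0 + d)
        m = ContactMatrix("chr1", 10_000, counts, np.ones(n, bool))
        exp = expected_by_distance(m)
        np.testing.assert_allclose(exp, 100.0 / (1.0 + np.arange(n)), rtol=1e-12)
        np.testing.assert_allclose(oe_matrix(m), 1.0, rtol=1e-12)
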
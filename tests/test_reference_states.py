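"""Probability normalizations and the five reference-state derivations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dockpot.pair_stats import DistanceBinning, PairCountTable
from dockpot.reference_states import (
    ProbabilityTable,
    derive,
    derive_contact,
    derive_ref1,
    derive_ref2,
    derive_ref3,
    derive_ref4,
    derive_ref5,
    energy_from_probs,
    prob_conditional_pair,
    prob_distance_marginal,
    prob_joint,
    read_potential,
    write_potential,
    _rebin_to_single,
)
from conftest import random_count_table

B21 = DistanceBinning(10.0, 21)


def delta_table(i=0, j=3, d=5, n=1, binning=B21):
    t = PairCountTable(binning=binning)
    t.counts[i, j, d] = n
    t.counts[j, i, d] = n
    t.n_pairs_per_bin = t.counts.sum(axis=(0, 1))
    t.n_residue[i] = 1
    t.n_residue[j] = 1
    return t


class TestProbabilityTables:
    def test_joint_delta(self):
        t = delta_table(i=0, j=3, n=1)
        pi = prob_joint(t)
        assert pi.pi[0, 3, 5] == 0.5 and pi.pi[3, 0, 5] == 0.5  # symmetric double count
        assert pi.pi.sum() == 1.0

    def test_joint_uniform(self):
        t = PairCountTable(binning=B21)
        t.counts[:] = 4
        t.n_pairs_per_bin = t.counts.sum(axis=(0, 1))
        pi = prob_joint(t)
        assert np.allclose(pi.pi, 1.0 / (60 * 60 * 21))

    def test_joint_normalization_on_random_table(self, rng):
        pi = prob_joint(random_count_table(rng))
        assert abs(pi.pi.sum() - 1.0) < 1e-12

    def test_conditional_pair_direct(self):
        t = PairCountTable(binning=B21)
        t.counts[2, 7, :4] = [1, 1, 2, 0]
        t.counts[7, 2, :4] = [1, 1, 2, 0]
        t.n_pairs_per_bin = t.counts.sum(axis=(0, 1))
        pi = prob_conditional_pair(t)
        assert np.allclose(pi.pi[2, 7, :4], [0.25, 0.25, 0.5, 0.0])
        assert not pi.empty_pairs[2, 7]
        assert pi.empty_pairs[0, 0]
        assert pi.pi[0, 0].sum() == 0.0  # flagged empty, not zero-normalized

    def test_conditional_pair_sums_to_one(self, rng):
        t = random_count_table(rng)
        pi = prob_conditional_pair(t)
        sums = pi.pi.sum(axis=2)
        assert np.allclose(sums[~pi.empty_pairs], 1.0, atol=1e-12)

    def test_distance_marginal(self, rng):
        t = random_count_table(rng)
        f = prob_distance_marginal(t)
        brute = t.counts.sum(axis=(0, 1)) / t.counts.sum()
        assert np.allclose(f, brute, atol=1e-12)
        t2 = delta_table(d=0)
        assert prob_distance_marginal(t2)[0] == 1.0

    def test_empty_tables_rejected(self):
        empty = PairCountTable(binning=B21)
        for fn in (prob_joint, prob_distance_marginal):
            with pytest.raises(ValueError):
                fn(empty)


class TestEnergyFromProbs:
    def test_log_ratio_values(self):
        shape = (60, 60, 21)
        obs = ProbabilityTable(np.full(shape, 0.1), "joint", B21)
        exp = ProbabilityTable(np.full(shape, 0.1), "joint", B21)
        pot = energy_from_probs(obs, exp)
        assert np.all(pot.energies == 0.0)
        obs2 = ProbabilityTable(np.full(shape, 0.2), "joint", B21)
        pot2 = energy_from_probs(obs2, exp)
        assert np.allclose(pot2.energies, -np.log(2.0))

    def test_observed_zero_is_capped_not_infinite(self):
        shape = (60, 60, 21)
        po = np.full(shape, 0.1)
        po[0, 0, 0] = 0.0
        obs = ProbabilityTable(po, "joint", B21)
        exp = ProbabilityTable(np.full(shape, 0.1), "joint", B21)
        pot = energy_from_probs(obs, exp, energy_cap=10.0)
        assert pot.energies[0, 0, 0] == 10.0
        assert np.all(np.isfinite(pot.energies))

    def test_shape_mismatch_rejected(self):
        obs = ProbabilityTable(np.full((60, 60, 21), 0.1), "joint", B21)
        exp = ProbabilityTable(np.full((60, 60, 5), 0.1), "joint", DistanceBinning(10.0, 5))
        with pytest.raises(ValueError):
            energy_from_probs(obs, exp)


class TestZeroEnergyIdentity:
    """Identical observed/expected statistics must give identically zero tables."""

    def test_two_table_states(self, rng):
        t = random_count_table(rng)
        for fn in (derive_ref1, derive_ref5, ):
            pot = fn(t, t)
            assert np.abs(pot.energies).max() < 1e-9, fn.__name__

    def test_contact_state(self, rng):
        t = random_count_table(rng, binning=DistanceBinning(8.0, 21))
        pot = derive_contact(t, t)
        assert np.abs(pot.energies).max() < 1e-9

    def test_ref2_degenerate_single_type(self):
        # one type only (chi = 1), all pairs of that type, every bin equally:
        # pi_obs = 1 = chi*chi -> e = 0 (no-pseudocount arithmetic)
        t = PairCountTable(binning=B21)
        t.counts[0, 0, :] = 10
        t.n_pairs_per_bin = t.counts.sum(axis=(0, 1))
        t.n_residue[0] = 40
        pot = derive_ref2(t, pseudocount=0.0)
        assert np.abs(pot.energies).max() < 1e-12

    def test_ref3_no_data_collapses_to_reference(self, rng):
        t = random_count_table(rng)
        t.counts[10, 20, :] = 0
        t.counts[20, 10, :] = 0
        t.n_pairs_per_bin = t.counts.sum(axis=(0, 1))
        pot = derive_ref3(t)
        assert np.abs(pot.energies[10, 20]).max() == 0.0

    def test_ref4_single_type_alphabet(self):
        # alphabet collapsed to one type: g == f -> e == 0
        t = PairCountTable(binning=B21)
        t.counts[0, 0, :] = np.arange(1, 22)
        t.n_pairs_per_bin = t.counts.sum(axis=(0, 1))
        t.n_residue[0] = 10
        pot = derive_ref4(t, pseudocount=0.0)
        assert np.abs(pot.energies[0, 0]).max() < 1e-12


class TestHandArithmetic:
    def test_ref2_hand_example(self):
        """chi_a = chi_b = 0.5 and N(a,b,d)/N(d) = 0.5 -> e = -ln 2."""
        t = PairCountTable(binning=B21)
        a, b = 0, 3
        t.counts[a, b, :] = 5
        t.counts[b, a, :] = 5  # N(d) = 10 ordered pairs -> pi_obs(a,b,d) = 0.5
        t.n_pairs_per_bin = t.counts.sum(axis=(0, 1))
        t.n_residue[a] = 30
        t.n_residue[b] = 30
        pot = derive_ref2(t, pseudocount=0.0)
        assert np.allclose(pot.energies[a, b], -np.log(2.0))

    def test_ref5_hand_example(self):
        """2-type, 3-bin counts: e = -ln(g_near / g_decoy) cell by cell."""
        b3 = DistanceBinning(10.0, 3)
        near = PairCountTable(binning=b3)
        dec = PairCountTable(binning=b3)
        near.counts[0, 3] = near.counts[3, 0] = [6, 2, 2]
        dec.counts[0, 3] = dec.counts[3, 0] = [2, 4, 4]
        for t in (near, dec):
            t.n_pairs_per_bin = t.counts.sum(axis=(0, 1))
            t.n_residue[0] = t.n_residue[3] = 10
        pot = derive_ref5(near, dec, pseudocount=0.0)
        g_near = np.array([0.6, 0.2, 0.2])
        g_dec = np.array([0.2, 0.4, 0.4])
        assert np.allclose(pot.energies[0, 3], -np.log(g_near / g_dec))
        assert np.allclose(pot.energies[3, 0], pot.energies[0, 3])

    def test_ref1_cell_only_in_near_is_favorable(self, rng):
        near = random_count_table(rng, scale=5)
        dec = random_count_table(rng, scale=5)
        near.counts[1, 4, 2] += 500
        near.counts[4, 1, 2] += 500
        near.n_pairs_per_bin = near.counts.sum(axis=(0, 1))
        dec.counts[1, 4, 2] = dec.counts[4, 1, 2] = 0
        dec.n_pairs_per_bin = dec.counts.sum(axis=(0, 1))
        pot = derive_ref1(near, dec)
        assert pot.energies[1, 4, 2] < 0

    def test_ref4_sign_pattern_short_vs_long(self):
        """A pair concentrated at short range scores negative there and
        positive at long range, against a flat marginal."""
        t = PairCountTable(binning=B21)
        t.counts[:, :, :] = 10  # flat background -> flat f(d)
        t.counts[0, 3, :] = 1
        t.counts[3, 0, :] = 1
        t.counts[0, 3, 0] = 200
        t.counts[3, 0, 0] = 200
        t.n_pairs_per_bin = t.counts.sum(axis=(0, 1))
        pot = derive_ref4(t)
        assert pot.energies[0, 3, 0] < 0
        assert np.all(pot.energies[0, 3, 5:] > 0)


class TestSippl:
    def test_equal_weights_at_m_50(self):
        """m_ij * sigma = 1 at m = 50, sigma = 0.02: f and g weighted 50/50."""
        t = random_count_table(np.random.default_rng(5), scale=20)
        i, j = 2, 9
        t.counts[i, j, :] = 0
        t.counts[j, i, :] = 0
        t.counts[i, j, 0] = 50
        t.counts[j, i, 0] = 50  # m_ij counts the (i,j) row: 50
        t.n_pairs_per_bin = t.counts.sum(axis=(0, 1))
        pot = derive_ref3(t, sigma=0.02, pseudocount=0.0)
        f = t.n_pairs_per_bin / t.n_pairs_per_bin.sum()
        g = t.counts[i, j] / t.counts[i, j].sum()
        expected = -np.log((0.5 * f + 0.5 * g) / f)
        assert np.allclose(pot.energies[i, j], np.clip(expected, -10, 10))

    def test_large_count_limit_converges_to_ref4(self):
        """With ~1e6 counts per pair the Sippl blend matches the plain
        conditional-vs-marginal ratio to 1e-3."""
        rng = np.random.default_rng(7)
        t = random_count_table(rng, scale=30000, min_count=20000)
        p3 = derive_ref3(t)
        p4 = derive_ref4(t)
        assert np.abs(p3.energies - p4.energies).max() < 1e-3

    def test_convex_interpolation_bounds(self, rng):
        """Every ref3 energy lies between the no-data limit (0) and the
        full-data limit (ref4), cell by cell."""
        t = random_count_table(rng, scale=40)
        e3 = derive_ref3(t).energies
        e4 = derive_ref4(t).energies
        lo = np.minimum(0.0, e4) - 1e-12
        hi = np.maximum(0.0, e4) + 1e-12
        assert np.all((e3 >= lo) & (e3 <= hi))


class TestContactEquivalence:
    def test_rebinned_ref5_equals_contact(self, rng, tmp_path):
        b8 = DistanceBinning(8.0, 21)
        near = random_count_table(rng, binning=b8)
        dec = random_count_table(rng, binning=b8)
        contact = derive_contact(near, dec)
        one = DistanceBinning(8.0, 1)
        direct = derive_ref5(_rebin_to_single(near, one), _rebin_to_single(dec, one))
        assert np.array_equal(contact.energies, direct.energies)
        # bit-identical after serialization at 6 decimals
        direct.reference_state = "contact"
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_potential(contact, p1)
        write_potential(direct, p2)
        assert p1.read_text() == p2.read_text()

    def test_contact_requires_8A_cutoff(self, rng):
        t = random_count_table(rng)  # 10 A cutoff
        with pytest.raises(ValueError):
            derive_contact(t, t)

    def test_planted_contact_enrichment_is_favorable(self, rng):
        b8 = DistanceBinning(8.0, 21)
        near = random_count_table(rng, binning=b8, scale=5)
        dec = random_count_table(rng, binning=b8, scale=5)
        near.counts[7, 11, :] += 300
        near.counts[11, 7, :] += 300
        near.n_pairs_per_bin = near.counts.sum(axis=(0, 1))
        pot = derive_contact(near, dec)
        assert pot.energies[7, 11, 0] < 0


class TestTableProperties:
    @given(st.integers(0, 2**31 - 1), st.sampled_from(["1", "2", "3", "4", "5"]))
    @settings(max_examples=30, deadline=None)
    def test_finite_and_symmetric_on_random_tables(self, seed, state):
        rng = np.random.default_rng(seed)
        near = random_count_table(rng, scale=rng.integers(1, 30))
        dec = random_count_table(rng, scale=rng.integers(1, 30))
        pot = derive(state, near, dec)
        assert np.all(np.isfinite(pot.energies))
        assert np.abs(pot.energies).max() <= pot.energy_cap
        assert np.array_equal(pot.energies, pot.energies.transpose(1, 0, 2))

    def test_dispatch_validates_state_and_decoys(self, rng):
        t = random_count_table(rng)
        with pytest.raises(ValueError):
            derive("9", t)
        with pytest.raises(ValueError):
            derive("5", t)  # decoys missing

    def test_binning_mismatch_rejected(self, rng):
        a = random_count_table(rng)
        b = random_count_table(rng, binning=DistanceBinning(10.0, 5))
        with pytest.raises(ValueError):
            derive_ref5(a, b)


class TestPotentialSerialization:
    def test_round_trip_at_six_decimals(self, rng, tmp_path):
        near = random_count_table(rng, scale=8)
        dec = random_count_table(rng, scale=8)
        pot = derive_ref5(near, dec)
        path = tmp_path / "pot.tsv"
        write_potential(pot, path)
        back = read_potential(path)
        assert back.binning == pot.binning
        assert back.reference_state == "5"
        assert np.abs(back.energies - pot.energies).max() <= 5e-7
        # writing the read-back table reproduces the file byte for byte
        path2 = tmp_path / "pot2.tsv"
        back.provenance = pot.provenance
        write_potential(back, path2)
        assert path.read_text() == path2.read_text()
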
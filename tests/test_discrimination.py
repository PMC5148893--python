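"""Probability vectors, Euclidean distances and the discrimination rule."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from barcodesig.discrimination import (
    compare_loci,
    discriminate_species,
    pairwise_distances,
    probability_vectors,
    DistanceMatrix,
    SeqProbVector,
)
from barcodesig.pssm import pssm
from barcodesig.records import BarcodeError
from conftest import make_alignment


class TestProbabilityVectors:
    def test_toy_vector_lookup(self, toy_alignment):
        m = pssm(toy_alignment)
        vs = probability_vectors(toy_alignment, m)
        np.testing.assert_allclose(vs[0].v, [0.75, 0.5, 1.0])  # ACG

    def test_identical_sequences_all_ones(self):
        aln = make_alignment(["ACGT"] * 3)
        vs = probability_vectors(aln, pssm(aln))
        for sv in vs:
            np.testing.assert_array_equal(sv.v, 1.0)

    def test_equal_frequency_collision_degeneracy(self, toy_alignment):
        # ACG and ATG get identical vectors: column 2 has C and T at 0.5 each
        m = pssm(toy_alignment)
        vs = probability_vectors(toy_alignment, m)
        np.testing.assert_array_equal(vs[0].v, vs[2].v)

    def test_length_mismatch_rejected(self, toy_alignment):
        m = pssm(make_alignment(["ACGT", "ACGT"]))
        with pytest.raises(BarcodeError, match="length"):
            probability_vectors(toy_alignment, m)


def naive_distances(vectors):
    n = len(vectors)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = np.sqrt(((vectors[i].v - vectors[j].v) ** 2).sum())
    return d


class TestPairwiseDistances:
    def test_toy_hand_computation(self, toy_alignment):
        m = pssm(toy_alignment)
        dm = pairwise_distances(probability_vectors(toy_alignment, m))
        # ACG vs TTG: only column 1 differs in probability (0.75 vs 0.25)
        assert dm[("S0", "S3")] == pytest.approx(0.5)
        assert dm[("S0", "S1")] == 0.0

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(7)
        vs = [SeqProbVector(f"v{i}", rng.random(11)) for i in range(5)]
        dm = pairwise_distances(vs)
        np.testing.assert_allclose(dm.d, naive_distances(vs), atol=1e-12)

    @given(st.integers(0, 2**32 - 1))
    def test_metric_axioms(self, seed):
        rng = np.random.default_rng(seed)
        vs = [SeqProbVector(f"v{i}", rng.random(8)) for i in range(6)]
        d = pairwise_distances(vs).d
        np.testing.assert_allclose(d, d.T, atol=1e-12)       # symmetry
        assert np.all(np.diag(d) == 0)                        # identity
        for i, j, k in itertools.permutations(range(6), 3):   # triangle
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-9


def dm_from(ids, mat):
    return DistanceMatrix(ids=tuple(ids), d=np.asarray(mat, dtype=float))


class TestDiscriminationRule:
    def test_zero_inter_distance_never_discriminates(self):
        # sequences collapsing to identical vectors: min_inter = 0
        dm = dm_from("abcd", np.zeros((4, 4)))
        labels = {"a": "P", "b": "P", "c": "Q", "d": "Q"}
        rep = discriminate_species(dm, labels)
        assert rep.pairs[0].discriminated is False
        assert rep.n_discriminated == 0 and rep.n_not == 2

    def test_clear_barcoding_gap(self, toy_alignment):
        # P = {ACG, ACG}, Q = {TTG, TTG} scored under the toy PPM:
        # intra 0 for both, inter 0.5 > 0 -> discriminated
        m = pssm(toy_alignment)
        aln = make_alignment(
            ["ACG", "ACG", "TTG", "TTG"],
            species=["P x", "P x", "Q y", "Q y"],
        )
        dm = pairwise_distances(probability_vectors(aln, m))
        rep = discriminate_species(dm, {r.id: r.species for r in aln.records})
        assert rep.pairs[0].discriminated is True
        assert rep.n_discriminated == 2

    def test_tie_between_inter_and_intra_fails(self):
        d = [
            [0.0, 0.4, 0.4, 0.5],
            [0.4, 0.0, 0.5, 0.4],
            [0.4, 0.5, 0.0, 0.1],
            [0.5, 0.4, 0.1, 0.0],
        ]
        labels = {"a": "P", "b": "P", "c": "Q", "d": "Q"}
        rep = discriminate_species(dm_from("abcd", d), labels)
        # min_inter = 0.4 equals max_intra(P) = 0.4: strict rule -> fail
        assert rep.pairs[0].discriminated is False

    def test_singleton_species_reduces_to_nonzero_inter(self):
        d = [[0.0, 0.3], [0.3, 0.0]]
        rep = discriminate_species(dm_from("ab", d), {"a": "P", "b": "Q"})
        assert rep.pairs[0].max_intra_a == 0.0
        assert rep.pairs[0].discriminated is True

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(3)
        raw = rng.random((6, 6))
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0)
        ids = ["q", "w", "e", "r", "t", "y"]
        labels = {"q": "A", "w": "A", "e": "B", "r": "B", "t": "C", "y": "C"}
        rep1 = discriminate_species(dm_from(ids, d), labels)
        perm = [3, 1, 5, 0, 4, 2]
        ids2 = [ids[i] for i in perm]
        d2 = d[np.ix_(perm, perm)]
        rep2 = discriminate_species(dm_from(ids2, d2), labels)
        assert rep1.species_table == rep2.species_table

    def test_added_close_pair_only_breaks_never_fixes(self):
        # adding an inter-species distance below max_intra flips a pair
        # from discriminated to not, never the reverse
        labels3 = {"a": "P", "b": "P", "c": "Q"}
        d3 = [[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]]
        before = discriminate_species(dm_from("abc", d3), labels3)
        assert before.pairs[0].discriminated is True
        labels4 = dict(labels3, d="Q")
        d4 = [
            [0.0, 0.2, 0.6, 0.1],
            [0.2, 0.0, 0.6, 0.1],
            [0.6, 0.6, 0.0, 0.3],
            [0.1, 0.1, 0.3, 0.0],
        ]
        after = discriminate_species(dm_from("abcd", d4), labels4)
        assert after.pairs[0].discriminated is False

    def test_pair_policies_differ_on_mixed_outcomes(self):
        # species A discriminated from B but not C
        d = [
            [0.0, 0.0, 0.5, 0.5, 0.0, 0.0],
            [0.0, 0.0, 0.5, 0.5, 0.0, 0.0],
            [0.5, 0.5, 0.0, 0.0, 0.5, 0.5],
            [0.5, 0.5, 0.0, 0.0, 0.5, 0.5],
            [0.0, 0.0, 0.5, 0.5, 0.0, 0.0],
            [0.0, 0.0, 0.5, 0.5, 0.0, 0.0],
        ]
        ids = list("abcdef")
        labels = dict(zip(ids, ["A", "A", "B", "B", "C", "C"]))
        strict = discriminate_species(dm_from(ids, d), labels, pair_policy="all")
        loose = discriminate_species(dm_from(ids, d), labels, pair_policy="any")
        assert strict.species_table["A"] is False
        assert loose.species_table["A"] is True

    def test_unlabelled_id_rejected(self):
        with pytest.raises(BarcodeError, match="unlabelled"):
            discriminate_species(dm_from("ab", np.zeros((2, 2))), {"a": "P"})


class TestCompareLoci:
    def test_equal_lists_give_p_one(self):
        with pytest.warns(UserWarning, match="zero"):
            out = compare_loci([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert out["p"] == 1.0

    def test_constant_shift_detected(self):
        a = [0.1 * i for i in range(1, 21)]
        b = [x + 0.1 for x in a]
        assert compare_loci(a, b)["p"] < 0.05

    def test_small_n_matches_exact_sign_enumeration(self):
        # n = 3: enumerate all 2^3 sign assignments of the ranked |d|
        a, b = [0.5, 0.1, 0.45], [0.2, 0.2, 0.2]
        d = np.array(a) - np.array(b)
        ranks = np.argsort(np.argsort(np.abs(d))) + 1
        w_obs = ranks[d > 0].sum()
        dist = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=3)
        ]
        n = len(dist)
        p_exact = min(
            1.0,
            2 * min(
                sum(w <= w_obs for w in dist) / n,
                sum(w >= w_obs for w in dist) / n,
            ),
        )
        assert compare_loci(a, b)["p"] == pytest.approx(p_exact)

    def test_length_mismatch_rejected(self):
        with pytest.raises(BarcodeError, match="unequal"):
            compare_loci([1.0], [1.0, 2.0])
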
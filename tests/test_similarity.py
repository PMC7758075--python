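import itertools
import math

import numpy as np
import pytest

from lpiskf import (alignment_similarity, expression_similarity, gip_kernel,
                    lncrna_nucleotide_features, lns_similarity,
                    pairwise_bitscores, protein_ctd_features)
from lpiskf.datasets import (BitscoreMatrix, ExpressionProfiles,
                             InteractionDataset, SequenceSet)
from lpiskf.similarity import CTD_PROPERTIES, FeatureTable


def _ds(A):
    A = np.asarray(A, dtype=float)
    return InteractionDataset([f"L{i}" for i in range(A.shape[0])],
                              [f"P{j}" for j in range(A.shape[1])], A)


class TestGip:
    def test_identity_adjacency_hand_value(self):
        # gamma = 2 / (1 + 1) = 1; ||row1 - row2||^2 = 2
        k = gip_kernel(_ds(np.eye(2)), "lncrna")
        assert k.scale_gamma == pytest.approx(1.0)
        assert k.values[0, 1] == pytest.approx(math.exp(-2), abs=1e-12)
        assert k.values[0, 0] == 1.0

    def test_diagonal_one_and_symmetric(self, rng):
        A = (rng.random((8, 5)) < 0.4).astype(float)
        A[0, 0] = 1  # avoid all-zero
        for axis in ("lncrna", "protein"):
            k = gip_kernel(_ds(A), axis)
            np.testing.assert_allclose(np.diag(k.values), 1.0)
            np.testing.assert_array_equal(k.values, k.values.T)
            assert ((k.values >= 0) & (k.values <= 1)).all()

    def test_all_zero_adjacency_errors(self):
        with pytest.raises(ValueError, match="division by zero"):
            gip_kernel(_ds(np.zeros((3, 2))), "lncrna")

    def test_permutation_equivariance(self, rng):
        A = (rng.random((7, 4)) < 0.5).astype(float)
        A[:, 0] = 1
        perm = rng.permutation(7)
        k = gip_kernel(_ds(A), "lncrna").values
        k_perm = gip_kernel(_ds(A[perm]), "lncrna").values
        np.testing.assert_allclose(k_perm, k[np.ix_(perm, perm)], atol=1e-12)


class TestExpression:
    def test_perfect_correlation(self):
        prof = ExpressionProfiles(["u", "v"], [[1, 2, 3], [2, 4, 6]])
        s = expression_similarity(prof).values
        assert s[0, 1] == pytest.approx(1.0)

    def test_anticorrelation(self):
        prof = ExpressionProfiles(["u", "v"], [[1, 2, 3], [3, 2, 1]])
        s = expression_similarity(prof).values
        assert s[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_zero(self, rng):
        prof = ExpressionProfiles([f"L{i}" for i in range(5)], rng.standard_normal((5, 6)))
        s = expression_similarity(prof).values
        np.testing.assert_array_equal(np.diag(s), 0.0)
        np.testing.assert_allclose(s, s.T)

    def test_zero_variance_profile_gets_zero(self):
        prof = ExpressionProfiles(["a", "b", "c"], [[1, 1, 1], [1, 2, 3], [3, 1, 2]])
        s = expression_similarity(prof).values
        assert (s[0] == 0).all() and (s[:, 0] == 0).all()


class TestAlignment:
    def test_ratio_and_asymmetry(self):
        b = BitscoreMatrix(["P1", "P2"], [[50, 20], [18, 40]])
        s = alignment_similarity(b).values
        assert s[0, 1] == pytest.approx(0.4)
        assert s[1, 0] == pytest.approx(0.45)
        np.testing.assert_array_equal(np.diag(s), 0.0)

    def test_self_score_ratio_one(self):
        b = BitscoreMatrix(["P1", "P2"], [[50, 50], [10, 40]])
        assert alignment_similarity(b).values[0, 1] == 1.0

    def test_overshoot_clipped(self):
        b = BitscoreMatrix(["P1", "P2"], [[50, 60], [10, 40]])
        assert alignment_similarity(b).values[0, 1] == 1.0

    def test_zero_self_score_errors(self):
        b = BitscoreMatrix(["P1", "P2"], [[0, 5], [5, 40]])
        with pytest.raises(ValueError, match="P1"):
            alignment_similarity(b)


class TestPairwiseBitscores:
    def test_self_alignment_equals_and_hand_score(self):
        from Bio.Align import substitution_matrices

        seqs = SequenceSet({"P1": "ACD", "P2": "ACD", "P3": "WWWW"},
                           axis="protein", alphabet="protein")
        b = pairwise_bitscores(seqs)
        i, j = b.ids.index("P1"), b.ids.index("P2")
        assert b.values[i, j] == pytest.approx(b.values[i, i])
        # raw self score of ACD = sum of diagonal BLOSUM62 entries
        m = substitution_matrices.load("BLOSUM62")
        raw = m["A", "A"] + m["C", "C"] + m["D", "D"]
        expected = (0.3176 * raw - math.log(0.134)) / math.log(2)
        assert b.values[i, i] == pytest.approx(expected, rel=1e-12)

    def test_downstream_similarity_small_for_unrelated(self):
        seqs = SequenceSet({"P1": "AAAAAAAA", "P2": "WWWWWWWW"},
                           axis="protein", alphabet="protein")
        s = alignment_similarity(pairwise_bitscores(seqs)).values
        assert 0 <= s[0, 1] < 0.5


class TestNucleotideFeatures:
    def test_hand_counts(self):
        seqs = SequenceSet({"L1": "ACGU"}, axis="lncrna", alphabet="rna")
        x = lncrna_nucleotide_features(seqs).values[0]
        np.testing.assert_allclose(x[:4], 0.25)
        di = dict(zip(["".join(p) for p in itertools.product("ACGU", repeat=2)], x[4:]))
        for d in ("AC", "CG", "GU"):
            assert di[d] == pytest.approx(1 / 3)
        assert sum(v for k, v in di.items() if k not in ("AC", "CG", "GU")) == 0

    def test_homopolymer(self):
        seqs = SequenceSet({"L1": "AAAA"}, axis="lncrna", alphabet="rna")
        x = lncrna_nucleotide_features(seqs).values[0]
        assert x[0] == 1.0 and x[4] == 1.0

    def test_blocks_normalized(self, rng):
        letters = np.array(list("ACGU"))
        seqs = SequenceSet({f"L{i}": "".join(rng.choice(letters, size=30)) for i in range(4)},
                           axis="lncrna", alphabet="rna")
        X = lncrna_nucleotide_features(seqs).values
        np.testing.assert_allclose(X[:, :4].sum(axis=1), 1.0)
        np.testing.assert_allclose(X[:, 4:].sum(axis=1), 1.0)

    def test_length_one_rejected(self):
        seqs = SequenceSet({"L1": "A"}, axis="lncrna", alphabet="rna")
        with pytest.raises(ValueError, match="too short"):
            lncrna_nucleotide_features(seqs)


class TestCtdFeatures:
    def test_single_group_sequence(self):
        # all residues in hydrophobicity group 1 (RKEDQN)
        seqs = SequenceSet({"P1": "RKED"}, axis="protein", alphabet="protein")
        X = protein_ctd_features(seqs, properties={"hydro": CTD_PROPERTIES["hydrophobicity"]})
        x = X.values[0]
        np.testing.assert_allclose(x[:3], [1, 0, 0])
        np.testing.assert_allclose(x[3:6], 0.0)
        # group-1 distribution quantiles: positions 1..4 of 4 -> 1/4, 1/4, 2/4, 3/4, 1
        np.testing.assert_allclose(x[6:11], [0.25, 0.25, 0.5, 0.75, 1.0])

    def test_default_dimension_84(self, small_study):
        X = protein_ctd_features(small_study.protein_sequences)
        assert X.dim == 84

    def test_blocks_normalized(self, rng):
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        seqs = SequenceSet({f"P{i}": "".join(rng.choice(letters, size=40)) for i in range(3)},
                           axis="protein", alphabet="protein")
        X = protein_ctd_features(seqs).values
        for p in range(4):
            comp = X[:, 21 * p: 21 * p + 3]
            np.testing.assert_allclose(comp.sum(axis=1), 1.0)


from conftest import exhaustive_qp_oracle


class TestLns:
    def test_duplicate_neighbor_takes_all_weight(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [6.0, -3.0]])
        feats = FeatureTable([f"e{i}" for i in range(4)], X, axis="protein")
        s = lns_similarity(feats, k=3).values
        assert s[0, 1] == pytest.approx(1.0, abs=1e-6)
        assert s[0, 2] == pytest.approx(0.0, abs=1e-6)

    def test_rows_sum_to_one_diag_zero(self, rng):
        X = rng.standard_normal((9, 4))
        feats = FeatureTable([f"e{i}" for i in range(9)], X, axis="lncrna")
        s = lns_similarity(feats, k=4).values
        np.testing.assert_allclose(s.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_array_equal(np.diag(s), 0.0)
        assert ((s >= 0) & (s <= 1 + 1e-12)).all()

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_qp_oracle(self, seed):
        # 4-D features with 3 neighbors: the target generically lies outside
        # the neighbors' affine hull, so the constrained optimum is unique
        # and the weight comparison is well-posed.
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((6, 4))
        feats = FeatureTable([f"e{i}" for i in range(6)], X, axis="protein")
        k = 3
        s = lns_similarity(feats, k=k).values
        for u in range(6):
            d2 = ((X - X[u]) ** 2).sum(axis=1)
            d2[u] = np.inf
            nbr = np.lexsort((np.arange(6), d2))[:k]
            w_oracle = exhaustive_qp_oracle(X[u], X[nbr])
            np.testing.assert_allclose(s[u, nbr], w_oracle, atol=1e-6)

    @pytest.mark.parametrize("seed", range(3))
    def test_objective_optimal_vs_oracle(self, seed):
        # In low feature dimension the optimum can be non-unique; the
        # implementation must still attain the oracle's optimal objective.
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((6, 2))
        feats = FeatureTable([f"e{i}" for i in range(6)], X, axis="protein")
        s = lns_similarity(feats, k=5).values
        for u in range(6):
            d2 = ((X - X[u]) ** 2).sum(axis=1)
            d2[u] = np.inf
            nbr = np.lexsort((np.arange(6), d2))[:5]
            w_oracle = exhaustive_qp_oracle(X[u], X[nbr])
            diff = X[u][None, :] - X[nbr]
            G = diff @ diff.T
            w_impl = s[u, nbr]
            assert w_impl @ G @ w_impl <= w_oracle @ G @ w_oracle + 1e-6

    def test_k_bounds(self):
        feats = FeatureTable(["a", "b"], np.eye(2), axis="protein")
        with pytest.raises(ValueError):
            lns_similarity(feats, k=2)
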
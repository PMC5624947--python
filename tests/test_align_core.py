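import numpy as np
import pytest
from hypothesis import given, strategies as st

from memsa.align_core import (
    DistanceMatrix,
    Profile,
    build_distance_matrix,
    kmer_distance,
    pairwise_align,
    profile_align,
    progressive_align,
    upgma,
)
from memsa.score_model import GapModel
from memsa.seqio import SequenceRecord

from oracles import (
    brute_force_alignment_score,
    naive_shape,
    naive_upgma,
    score_emitted_alignment,
    tree_shape,
)


class TestPairwiseAlign:
    def test_identical_sequences_score_sum_of_diagonal(self, blosum62, default_gaps):
        score, aln = pairwise_align("AAAA", "AAAA", blosum62, default_gaps)
        assert score == 16
        assert [r for _, r in aln.rows] == ["AAAA", "AAAA"]

    def test_empty_against_single_residue(self, blosum62, default_gaps):
        score, aln = pairwise_align("", "A", blosum62, default_gaps)
        assert score == -8
        assert [r for _, r in aln.rows] == ["-", "A"]

    @given(
        a=st.text(alphabet="ACDE", min_size=0, max_size=6),
        b=st.text(alphabet="ACDE", min_size=0, max_size=6),
    )
    def test_score_matches_exhaustive_enumeration(self, blosum62, default_gaps, a, b):
        if not a and not b:
            return
        score, _ = pairwise_align(a, b, blosum62, default_gaps)
        assert score == brute_force_alignment_score(a, b, blosum62, default_gaps)

    @given(
        a=st.text(alphabet="ACDEFGHIKL", min_size=1, max_size=12),
        b=st.text(alphabet="ACDEFGHIKL", min_size=1, max_size=12),
    )
    def test_emitted_alignment_rescores_to_reported_score(
        self, blosum62, default_gaps, a, b
    ):
        """Score/alignment consistency: integer re-scoring of the emitted
        rows reproduces the DP score exactly."""
        score, aln = pairwise_align(a, b, blosum62, default_gaps)
        row_a, row_b = (r for _, r in aln.rows)
        assert score == score_emitted_alignment(row_a, row_b, blosum62, default_gaps)

    @given(
        a=st.text(alphabet="ACDEFG", min_size=1, max_size=15),
        b=st.text(alphabet="ACDEFG", min_size=1, max_size=15),
    )
    def test_traceback_consumes_both_sequences_exactly(self, blosum62, default_gaps, a, b):
        """The branch-matrix walk reaches (0,0): ops consume exactly the
        input lengths and every row degaps to its input."""
        _, aln = pairwise_align(a, b, blosum62, default_gaps)
        row_a, row_b = (r for _, r in aln.rows)
        assert row_a.replace("-", "") == a
        assert row_b.replace("-", "") == b
        assert len(row_a) == len(row_b)

    def test_free_end_gaps_cost_nothing(self, blosum62, default_gaps):
        from memsa.align_core import affine_dp

        ia = np.array([[4, 4], [4, 4], [4, 4], [4, 4]])  # 4x2 all-match toy
        score, ops = affine_dp(ia, 8, 1, free_ends=True)
        assert score == 8  # two matches, overhang free
        assert ops.count("D") == 2 and ops.count("U") == 2


class TestKmerDistance:
    def test_identity_is_zero(self):
        assert kmer_distance("ACDEFG", "ACDEFG") == 0.0

    def test_disjoint_kmer_sets(self):
        assert kmer_distance("AAAA", "CCCC", 3) == 1.0

    def test_shared_fraction(self):
        assert kmer_distance("ACDE", "CDEF", 3) == 0.5

    def test_k_clamped_for_short_sequences(self):
        assert kmer_distance("AC", "AC", 3) == 0.0

    def test_symmetric_and_bounded(self):
        d1 = kmer_distance("ACDEFGHIK", "MKLVFF")
        d2 = kmer_distance("MKLVFF", "ACDEFGHIK")
        assert d1 == d2 and 0.0 <= d1 <= 1.0


class TestDistanceMatrix:
    def test_identical_pair_distance_zero(self):
        dm = build_distance_matrix([("a", "ACDEF"), ("b", "ACDEF")])
        assert dm.d[0, 1] == 0.0

    def test_pattern_with_outlier(self):
        dm = build_distance_matrix(
            [("a", "ACDEFG"), ("b", "ACDEFG"), ("c", "KKKKKK")]
        )
        assert dm.d[0, 1] == 0.0
        assert dm.d[0, 2] == 1.0 and dm.d[1, 2] == 1.0

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            build_distance_matrix([("a", "ACDEF")])


class TestUpgma:
    def test_two_leaves_join_at_half_distance(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 0.4], [0.4, 0]]))
        tree = upgma(dm)
        assert tree.root.height == pytest.approx(0.2)
        assert sorted(tree.leaf_names()) == ["A", "B"]

    def test_three_leaves_weighted_average(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = upgma(DistanceMatrix(["A", "B", "C"], d))
        assert tree.root.height == pytest.approx(2.0)
        inner = [c for c in tree.root.children if not c.is_leaf][0]
        assert inner.height == pytest.approx(1.0)
        assert sorted(inner.leaf_names()) == ["A", "B"]

    def test_all_equal_distances_merge_in_index_order(self):
        n = 4
        d = np.ones((n, n)) - np.eye(n)
        ids = list("ABCD")
        tree = upgma(DistanceMatrix(ids, d))
        assert tree_shape(tree.root) == naive_shape(naive_upgma(ids, d))

    @pytest.mark.parametrize("seed", range(10))
    def test_rowmin_matches_naive_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 15))
        d = rng.random((n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        ids = [f"t{i}" for i in range(n)]
        assert tree_shape(upgma(DistanceMatrix(ids, d)).root) == naive_shape(
            naive_upgma(ids, d)
        )

    def test_newick_export_has_all_leaves(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        nwk = upgma(DistanceMatrix(["A", "B", "C"], d)).to_newick()
        assert nwk.endswith(";")
        for leaf in "ABC":
            assert leaf in nwk


class TestProfileAlign:
    def test_single_row_profiles_reduce_to_pairwise(self, blosum62, default_gaps):
        score_pw, aln = pairwise_align("ACDE", "ADE", blosum62, default_gaps)
        res = profile_align(
            Profile.from_sequence("a", "ACDE"),
            Profile.from_sequence("b", "ADE"),
            blosum62,
            default_gaps,
        )
        assert res.score == score_pw
        assert [r for _, r in res.profile.rows] == [r for _, r in aln.rows]

    def test_identical_profiles_need_no_new_gaps(self, blosum62, default_gaps):
        res = profile_align(
            Profile.from_sequence("a", "ACDE"),
            Profile.from_sequence("b", "ACDE"),
            blosum62,
            default_gaps,
        )
        assert res.profile.width == 4
        assert res.ops == "DDDD"

    def test_existing_gaps_are_preserved(self, blosum62, default_gaps):
        p = Profile([("a", "AC-E"), ("b", "ACDE")])
        q = Profile.from_sequence("c", "ACE")
        res = profile_align(p, q, blosum62, default_gaps)
        merged = dict(res.profile.rows)
        assert merged["a"].replace("-", "") == "ACE"
        assert merged["b"].replace("-", "") == "ACDE"
        assert merged["c"].replace("-", "") == "ACE"

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            Profile([])


class TestProgressiveAlign:
    def test_two_sequences_reduce_to_pairwise(self, blosum62, default_gaps):
        items = [("a", "ACDE"), ("b", "ADE")]
        tree = upgma(build_distance_matrix(items))
        aln = progressive_align(items, tree, blosum62, default_gaps)
        _, pw = pairwise_align("ACDE", "ADE", blosum62, default_gaps)
        assert sorted(r for _, r in aln.rows) == sorted(r for _, r in pw.rows)

    def test_identical_sequences_stay_gapless(self, blosum62, default_gaps):
        items = [(f"s{i}", "MKLVAF") for i in range(4)]
        tree = upgma(build_distance_matrix(items))
        aln = progressive_align(items, tree, blosum62, default_gaps)
        assert aln.width == 6
        assert all(r == "MKLVAF" for _, r in aln.rows)

    def test_rows_follow_input_order(self, blosum62, default_gaps):
        items = [("z", "ACDE"), ("a", "ACE"), ("m", "KKDE")]
        tree = upgma(build_distance_matrix(items))
        aln = progressive_align(items, tree, blosum62, default_gaps)
        assert aln.ids == ["z", "a", "m"]

    def test_leaf_mismatch_rejected(self, blosum62, default_gaps):
        items = [("a", "ACDE"), ("b", "ADE")]
        tree = upgma(build_distance_matrix([("a", "ACDE"), ("c", "ADE")]))
        with pytest.raises(ValueError):
            progressive_align(items, tree, blosum62, default_gaps)

    def test_roundtrip_for_random_records(self, blosum62, default_gaps):
        rng = np.random.default_rng(5)
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        records = [
            SequenceRecord(
                f"r{i}",
                "".join(rng.choice(list(alphabet), size=rng.integers(4, 30))),
            )
            for i in range(6)
        ]
        tree = upgma(build_distance_matrix(records))
        aln = progressive_align(records, tree, blosum62, default_gaps)
        aln.check_roundtrip(records)
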
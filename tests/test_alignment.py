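"""Pairwise alignment: brute-force oracle equivalence, statistics, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import RES20, RES21, random_protein
from oracles import brute_force_global, brute_force_local
from tatscan.alignment import (
    AlignmentResult,
    ScoringScheme,
    align_global,
    align_local,
    bit_score,
    evalue,
)

protein = st.text(alphabet=RES21, min_size=1, max_size=30)


class TestOracleEquivalence:
    def test_dp_equals_brute_force_enumeration(self, scheme):
        """Global and local DP scores equal exhaustive path enumeration on
        >= 200 random short pairs (X included in the alphabet)."""
        rng = np.random.default_rng(101)
        for _ in range(220):
            a = random_protein(rng, int(rng.integers(1, 7)), RES21)
            b = random_protein(rng, int(rng.integers(1, 7)), RES21)
            assert align_global(a, b, scheme).raw_score == brute_force_global(a, b, scheme)
            assert align_local(a, b, scheme).raw_score == brute_force_local(a, b, scheme)

    def test_dp_agrees_with_biopython_at_realistic_lengths(self, scheme):
        """Independent cross-check against Bio.Align.PairwiseAligner for
        X-free sequences at family-typical lengths."""
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
        aligner.extend_gap_score = -scheme.gap_extend
        rng = np.random.default_rng(77)
        for mode, fn in (("global", align_global), ("local", align_local)):
            aligner.mode = mode
            for _ in range(15):
                a = random_protein(rng, int(rng.integers(40, 120)))
                b = random_protein(rng, int(rng.integers(40, 120)))
                assert fn(a, b, scheme).raw_score == aligner.score(a, b)


class TestGlobal:
    def test_identical_sequences_full_identity(self, scheme):
        res = align_global("MGEISITK", "MGEISITK", scheme)
        assert res.percent_identity == 100.0
        assert res.aligned_columns == 8
        assert res.raw_score == sum(scheme.score(c, c) for c in "MGEISITK")

    def test_single_substitution(self, scheme):
        res = align_global("MGEISITK", "MGGISITK", scheme)
        assert res.n_identical == 7
        assert res.percent_identity == pytest.approx(87.5)

    def test_gapped_alignment_recovers_sequences(self, scheme):
        res = align_global("MGEISITKLLVV", "MGEIKLLVV", scheme)
        assert res.aligned_query.replace("-", "") == "MGEISITKLLVV"
        assert res.aligned_subject.replace("-", "") == "MGEIKLLVV"
        assert len(res.aligned_query) == len(res.aligned_subject)

    def test_empty_sequence_rejected(self, scheme):
        with pytest.raises(ValueError):
            align_global("", "MGEISITK", scheme)


class TestLocal:
    def test_identical_60mers_span_full_length(self, scheme, rng):
        seq = random_protein(rng, 60)
        res = align_local(seq, seq, scheme)
        assert res.percent_identity == 100.0
        assert res.query_span == (1, 60)
        assert res.subject_span == (1, 60)

    def test_unrelated_homopolymers_match_oracle(self, scheme):
        res = align_local("MKKKKK", "MDDDDD", scheme)
        assert res.raw_score == brute_force_local("MKKKKK", "MDDDDD", scheme)

    def test_no_positive_pair_gives_empty_alignment(self):
        # a matrix where everything scores negative forces the empty alignment
        mat = np.full((21, 21), -1, dtype=np.int64)
        scheme = ScoringScheme(matrix=mat)
        res = align_local("KKKK", "DDDD", scheme)
        assert res.raw_score == 0
        assert res.aligned_query == ""
        assert res.query_span == (0, 0)
        assert res.percent_identity == 0.0

    def test_spans_recover_subsequences(self, scheme, rng):
        a = random_protein(rng, 50)
        b = a[10:40] + random_protein(rng, 20)
        res = align_local(a, b, scheme)
        q0, q1 = res.query_span
        s0, s1 = res.subject_span
        assert res.aligned_query.replace("-", "") == a[q0 - 1 : q1]
        assert res.aligned_subject.replace("-", "") == b[s0 - 1 : s1]


class TestProperties:
    @settings(max_examples=60, deadline=None)
    @given(a=protein, b=protein)
    def test_score_symmetry(self, a, b):
        scheme = ScoringScheme()
        assert align_global(a, b, scheme).raw_score == align_global(b, a, scheme).raw_score
        assert align_local(a, b, scheme).raw_score == align_local(b, a, scheme).raw_score

    @settings(max_examples=60, deadline=None)
    @given(a=st.text(alphabet=RES20, min_size=1, max_size=40))
    def test_self_alignment_scores_diagonal_sum(self, a):
        scheme = ScoringScheme()
        expected = sum(scheme.score(c, c) for c in a)
        assert align_global(a, a, scheme).raw_score == expected
        assert align_local(a, a, scheme).raw_score == max(expected, 0)

    @settings(max_examples=100, deadline=None)
    @given(a=protein, b=protein)
    def test_identity_bounds_and_equal_lengths(self, a, b):
        res = align_global(a, b, ScoringScheme())
        assert 0.0 <= res.percent_identity <= 100.0
        assert len(res.aligned_query) == len(res.aligned_subject)

    def test_x_never_inflates_identity(self, scheme):
        # X scores 0 against anything, so an all-X pair has local score 0
        assert align_local("MXXXXXXX", "MXXXXXXX", scheme).raw_score == scheme.score("M", "M")

    def test_deterministic_traceback(self, scheme, rng):
        a = random_protein(rng, 40)
        b = random_protein(rng, 40)
        r1 = align_global(a, b, scheme)
        r2 = align_global(a, b, scheme)
        assert r1 == r2


class TestStatistics:
    def test_evalue_fixed_point_is_one(self, scheme):
        m, n = 67, 10000
        s_star = math.log(scheme.kappa * m * n) / scheme.lambda_
        assert evalue(s_star, m, n, scheme) == pytest.approx(1.0)

    def test_evalue_linear_in_search_space(self, scheme):
        e1 = evalue(50, 67, 10000, scheme)
        e2 = evalue(50, 67, 20000, scheme)
        assert e2 == pytest.approx(2 * e1)

    def test_evalue_direct_evaluation(self, scheme):
        expected = 0.041 * 67 * 10000 * math.exp(-26.7)
        assert evalue(100, 67, 10000, scheme) == pytest.approx(expected, rel=1e-12)

    def test_evalue_monotone_decreasing_bit_score_increasing(self, scheme):
        scores = range(0, 200, 7)
        evs = [evalue(s, 67, 10000, scheme) for s in scores]
        bits = [bit_score(s, scheme) for s in scores]
        assert all(x > y for x, y in zip(evs, evs[1:]))
        assert all(x < y for x, y in zip(bits, bits[1:]))

    def test_nonpositive_lengths_rejected(self, scheme):
        with pytest.raises(ValueError):
            evalue(50, 0, 100, scheme)
        with pytest.raises(ValueError):
            evalue(50, 100, 0, scheme)


class TestScoringScheme:
    def test_asymmetric_matrix_rejected(self):
        mat = np.zeros((21, 21), dtype=np.int64)
        mat[0, 1] = 5
        with pytest.raises(ValueError, match="symmetric"):
            ScoringScheme(matrix=mat)

    def test_gap_extend_above_open_rejected(self):
        with pytest.raises(ValueError):
            ScoringScheme(gap_open=1, gap_extend=2)

    def test_tabular_export_columns(self, scheme):
        res = align_local("MGEISITK", "MGEISITK", scheme)
        fields = res.to_tabular().split("\t")
        assert len(fields) == 6
        assert fields[2] == "100.0"
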
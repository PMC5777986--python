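"""Synthetic family generator: determinism, ground truth, architecture."""

import math

import pytest

from tatscan.alignment import ScoringScheme, align_local
from tatscan.motif import MotifClass, classify
from tatscan.records import SequenceSet, write_fasta
from tatscan.simulate import (
    FamilySpec,
    build_survey_database,
    generate_decoys,
    generate_family,
    mutate,
    vibrionales_exemplar_octet,
)

ALL_CLASSES = [
    MotifClass.E3K8,
    MotifClass.E2K8,
    MotifClass.K8_ONLY,
    MotifClass.TATB_LIKE,
    MotifClass.TATA_LIKE,
    MotifClass.UNCHARGED_OTHER,
    MotifClass.OTHER_CHARGED,
    MotifClass.TOO_SHORT,
]


class TestGenerateFamily:
    @pytest.mark.parametrize("cls", ALL_CLASSES)
    def test_zero_noise_round_trip(self, cls):
        seqs, truth, _ = generate_family(FamilySpec(n_sequences=10, class_label=cls, seed=3))
        for rec, gt in zip(seqs, truth):
            assert gt.motif_class == cls
            assert classify(rec) == cls

    @pytest.mark.parametrize("cls", [c for c in ALL_CLASSES if c != MotifClass.TOO_SHORT])
    def test_protected_noise_round_trip(self, cls):
        seqs, truth, _ = generate_family(
            FamilySpec(n_sequences=10, class_label=cls, substitution_rate=0.3, seed=4)
        )
        for rec, gt in zip(seqs, truth):
            assert classify(rec) == gt.motif_class == cls

    def test_single_tata_like_sequence(self):
        seqs, _, _ = generate_family(FamilySpec(n_sequences=1, class_label=MotifClass.TATA_LIKE, seed=1))
        assert classify(seqs[0]) == MotifClass.TATA_LIKE

    def test_byte_level_seed_determinism(self, tmp_path):
        spec = FamilySpec(n_sequences=20, class_label=MotifClass.E3K8,
                          substitution_rate=0.2, seed=42, dual_paralog=True)
        out1, out2 = tmp_path / "a.faa", tmp_path / "b.faa"
        for out in (out1, out2):
            seqs, _, _ = generate_family(spec)
            write_fasta(seqs, out)
        assert out1.read_bytes() == out2.read_bytes()

    def test_different_seeds_differ(self):
        s1, _, _ = generate_family(FamilySpec(n_sequences=5, class_label=MotifClass.E3K8, seed=1))
        s2, _, _ = generate_family(FamilySpec(n_sequences=5, class_label=MotifClass.E3K8, seed=2))
        assert [r.sequence for r in s1] != [r.sequence for r in s2]

    def test_architecture_constraints(self):
        seqs, _, _ = generate_family(
            FamilySpec(n_sequences=10, class_label=MotifClass.TATA_LIKE,
                       length_range=(60, 80), seed=6)
        )
        for rec in seqs:
            assert rec.sequence[0] == "M"
            assert 60 <= len(rec) <= 80
            # transmembrane segment (positions 9..21 here) stays hydrophobic
            assert all(c in "AILVFG" for c in rec.sequence[8:21])

    def test_contradictory_spec_rejected(self):
        with pytest.raises(ValueError, match="contradictory"):
            FamilySpec(n_sequences=5, class_label=MotifClass.E3K8,
                       per_position_conservation={8: 0.0})

    def test_realized_conservation_converges_binomially(self):
        p = 0.99
        n = 1000
        seqs, _, _ = generate_family(
            FamilySpec(n_sequences=n, class_label=MotifClass.E3K8,
                       per_position_conservation={8: p}, seed=17,
                       length_range=(50, 60))
        )
        k = sum(1 for rec in seqs if rec.sequence[7] == "K")
        sigma = math.sqrt(n * p * (1 - p))
        assert abs(k - n * p) <= 3 * sigma

    def test_dual_paralog_mode_pairs_every_organism(self):
        seqs, truth, rows = generate_family(
            FamilySpec(n_sequences=7, class_label=MotifClass.E3K8, seed=8,
                       dual_paralog=True, taxon_order="Vibrionales")
        )
        assert len(seqs) == 14
        orgs = {}
        for gt in truth:
            orgs.setdefault(gt.organism, []).append(gt.motif_class)
        assert all(sorted(v, key=str) == [MotifClass.E3K8, MotifClass.TATA_LIKE] for v in orgs.values())
        assert len(rows) == 14


class TestDecoys:
    def test_zero_decoys(self):
        assert len(generate_decoys(0)) == 0

    def test_determinism(self):
        a = [r.sequence for r in generate_decoys(5, seed=9)]
        b = [r.sequence for r in generate_decoys(5, seed=9)]
        assert a == b

    def test_decoys_fail_evalue_cutoff_against_tate_like_query(self, scheme):
        seqs, _, _ = generate_family(
            FamilySpec(n_sequences=1, class_label=MotifClass.E3K8,
                       length_range=(67, 67), seed=2)
        )
        query = seqs[0]
        decoys = generate_decoys(5, length=100, seed=12)
        n_search = decoys.total_residues()
        for rec in decoys:
            e = align_local(query, rec, scheme, search_space=n_search).e_value
            assert e > 1e-3


class TestSurveyDatabase:
    def test_composition_and_truth_consistency(self):
        sdb = build_survey_database(seed=2)
        assert len(sdb.db) == len(sdb.truth) + 25  # 20 decoys + 5 incomplete
        for rid, cls in sdb.truth.items():
            assert classify(sdb.db[rid]) == cls

    def test_determinism_across_builds(self):
        a = build_survey_database(seed=3)
        b = build_survey_database(seed=3)
        assert [r.sequence for r in a.db] == [r.sequence for r in b.db]


class TestExemplarOctet:
    def test_documented_composition(self):
        tata1, tata2 = vibrionales_exemplar_octet(seed=1)
        classes = [classify(r) for r in tata1]
        assert classes.count(MotifClass.E3K8) == 7
        assert classes.count(MotifClass.K8_ONLY) == 1
        assert all(r.sequence[7] == "K" for r in tata1)
        assert min(len(r) for r in tata1) == 63
        assert max(len(r) for r in tata1) == 78
        assert all(classify(r) == MotifClass.TATA_LIKE for r in tata2)
        assert [r.organism for r in tata1] == [r.organism for r in tata2]
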
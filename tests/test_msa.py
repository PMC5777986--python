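"""Progressive MSA and consensus models: round-trips, column statistics."""

import math

import pytest

from conftest import random_protein
from tatscan.msa import (
    LOG2_20,
    MultipleAlignment,
    align_progressive,
    column_for_reference_position,
    consensus,
    logo_matrix,
    reference_coordinates,
)
from tatscan.motif import MotifClass
from tatscan.records import ProteinRecord, SequenceSet
from tatscan.simulate import FamilySpec, generate_family


def _set(seqs: dict[str, str]) -> SequenceSet:
    return SequenceSet(records=[ProteinRecord(k, v) for k, v in seqs.items()])


class TestAlignProgressive:
    def test_identical_family_aligns_gapless(self, scheme):
        seq = "MGEISITKLLVVAALVVLLF"
        msa = align_progressive(_set({f"S{i}": seq for i in range(5)}), scheme)
        assert msa.n_columns == len(seq)
        assert all(row == seq for row in msa.rows)

    def test_single_insertion_gives_one_gap_column(self, scheme):
        base = "MGEISITKLLVVAALVVLLF"
        withins = base[:10] + "W" + base[10:]
        msa = align_progressive(_set({"A": base, "B": withins, "C": base}), scheme)
        assert msa.n_columns == len(base) + 1
        assert msa.row_for("A").count("-") == 1
        assert msa.row_for("C").count("-") == 1
        assert msa.row_for("B").count("-") == 0

    def test_degap_round_trip(self, scheme, rng):
        seqs, _, _ = generate_family(
            FamilySpec(n_sequences=12, class_label=MotifClass.E3K8,
                       length_range=(55, 70), substitution_rate=0.15, seed=5)
        )
        msa = align_progressive(seqs, scheme)
        for i, rec in enumerate(seqs):
            assert msa.degapped(i) == rec.sequence

    def test_permutation_invariance_of_columns(self, scheme):
        seqs, _, _ = generate_family(
            FamilySpec(n_sequences=8, class_label=MotifClass.TATB_LIKE,
                       length_range=(50, 60), substitution_rate=0.2, seed=9)
        )
        msa1 = align_progressive(seqs, scheme)
        reversed_set = SequenceSet(records=list(seqs)[::-1])
        msa2 = align_progressive(reversed_set, scheme)
        assert consensus(msa1).consensus == consensus(msa2).consensus
        # same row content per record, independent of input order
        for rid in seqs.ids:
            assert msa1.row_for(rid) == msa2.row_for(rid)

    def test_fewer_than_two_sequences_rejected(self, scheme):
        with pytest.raises(ValueError):
            align_progressive(_set({"A": "MGEISITK"}), scheme)


class TestConsensus:
    def _column_msa(self, residues: list[str]) -> MultipleAlignment:
        return MultipleAlignment(
            record_ids=[f"S{i}" for i in range(len(residues))],
            rows=[r for r in residues],
        )

    def test_single_residue_column(self):
        model = consensus(self._column_msa(["K"] * 4))
        col = model.columns[0]
        assert col.consensus_residue == "K"
        assert col.conservation == 1.0
        assert col.information_content == pytest.approx(LOG2_20)

    def test_99_to_1_column(self):
        model = consensus(self._column_msa(["K"] * 99 + ["R"]))
        assert model.columns[0].consensus_residue == "K"
        assert model.columns[0].conservation == pytest.approx(0.99)

    def test_72_to_28_column(self):
        model = consensus(self._column_msa(["E"] * 72 + ["G"] * 28))
        assert model.columns[0].consensus_residue == "E"
        assert model.columns[0].conservation == pytest.approx(0.72)

    def test_all_gap_column_convention(self):
        msa = MultipleAlignment(record_ids=["A", "B"], rows=["K-", "K-"])
        col = consensus(msa).columns[1]
        assert col.consensus_residue == "-"
        assert col.conservation == 0.0
        assert col.information_content == 0.0

    def test_consensus_tie_broken_alphabetically(self):
        model = consensus(self._column_msa(["K", "A"]))
        assert model.columns[0].consensus_residue == "A"

    def test_frequencies_normalized_and_information_bounded(self, scheme, rng):
        seqs, _, _ = generate_family(
            FamilySpec(n_sequences=10, class_label=MotifClass.TATA_LIKE,
                       length_range=(50, 58), substitution_rate=0.3, seed=21)
        )
        model = consensus(align_progressive(seqs, scheme))
        for col in model.columns:
            assert sum(col.frequencies.values()) == pytest.approx(1.0)
            assert 0.0 <= col.information_content <= LOG2_20 + 1e-12
            if col.conservation == 1.0 and col.consensus_residue != "-":
                assert col.information_content == pytest.approx(LOG2_20)

    def test_realized_conservation_matches_generated_counts(self, scheme):
        """On a family with controlled conservation at positions 3 and 8, the
        consensus model reports exactly the realized residue counts."""
        seqs, _, _ = generate_family(
            FamilySpec(n_sequences=40, class_label=MotifClass.E3K8,
                       length_range=(55, 65), per_position_conservation={8: 0.9},
                       substitution_rate=0.1, seed=13)
        )
        k_count = sum(1 for rec in seqs if rec.sequence[7] == "K")
        msa = align_progressive(seqs, scheme)
        col8 = column_for_reference_position(msa, seqs.ids[0], 8)
        col = consensus(msa).columns[col8]
        assert col.consensus_residue == "K"
        assert col.conservation == pytest.approx(k_count / 40)


class TestLogoMatrix:
    def test_single_residue_column_full_height(self):
        model = consensus(MultipleAlignment(record_ids=["A"], rows=["K"]))
        entries = logo_matrix(model)[0]
        assert entries == [("K", pytest.approx(LOG2_20))]

    def test_uniform_column_zero_height(self):
        from conftest import RES20

        msa = MultipleAlignment(
            record_ids=[f"S{i}" for i in range(20)], rows=list(RES20)
        )
        entries = logo_matrix(consensus(msa))[0]
        assert all(h == pytest.approx(0.0) for _, h in entries)

    def test_two_residue_even_split(self):
        msa = MultipleAlignment(record_ids=["A", "B"], rows=["K", "R"])
        entries = logo_matrix(consensus(msa))[0]
        expected = 0.5 * (LOG2_20 - 1.0)
        assert dict(entries) == {
            "K": pytest.approx(expected),
            "R": pytest.approx(expected),
        }

    def test_heights_sum_to_information(self, scheme):
        seqs, _, _ = generate_family(
            FamilySpec(n_sequences=6, class_label=MotifClass.K8_ONLY,
                       length_range=(50, 50), substitution_rate=0.2, seed=31)
        )
        model = consensus(align_progressive(seqs, scheme))
        for col, entries in zip(model.columns, logo_matrix(model)):
            assert sum(h for _, h in entries) == pytest.approx(col.information_content)


class TestReferenceCoordinates:
    def test_reference_map_skips_gaps(self):
        msa = MultipleAlignment(record_ids=["R", "S"], rows=["MG-EK", "MGWEK"])
        assert reference_coordinates(msa, "R") == [1, 2, None, 3, 4]
        assert column_for_reference_position(msa, "R", 3) == 3
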
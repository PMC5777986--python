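"""Synthetic TatA-family protein generator with exact ground truth.

Sequences follow the family architecture: an initiator Met, a short
uncharged N-tail, a hydrophobic transmembrane segment starting near
position 4, an amphipathic helix of alternating hydrophobic/polar
residues, and a hydrophilic C-terminal tail, 50-180 residues in total.
The residues at positions 2, 3 and 8 are placed according to the target
motif class, so the generating label is known exactly for every record:

    E3K8            M G E I S I T K   (TatE-type, Gly-Glu pair)
    E2K8            M E G I S I T K   (TatE-type, Glu-Gly pair)
    K8_ONLY         M G A I S I T K
    TATB_LIKE       M F D I G F S E   (acidic residue 8)
    TATA_LIKE       M G G I S I W Q   (uncharged, polar Gln8)
    UNCHARGED_OTHER M G G I S I W A
    OTHER_CHARGED   M G E I S I T R

Per-position conservation probabilities control how often a member carries
the consensus residue: at position 3 of an E3K8 family the alternative is
the Glu2 arrangement (so a family generated with {3: 0.72} is a 72/28
mixture of Gly-Glu and Glu-Gly N-termini), and at position 8 the
alternative is Arg.  Substitution noise never touches positions 1-8 unless
``protect_motif`` is disabled, so motif ground truth stays exact under
noise.  All randomness flows from a single integer seed; identical seeds
give byte-identical FASTA/TSV output.

Families may share an ancestral template so that different subfamilies
remain detectably homologous to a common query -- the situation the
homology screen faces in a real database survey.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tatscan.motif import MotifClass
from tatscan.records import ProteinRecord, SequenceSet, Taxonomy

RES20 = "ACDEFGHIKLMNPQRSTVWY"
HYDROPHOBIC = "AILVFG"
POLAR = "STNQGH"
TAIL = "ADEGKNPQST"

_FIRST8 = {
    MotifClass.E3K8: "MGEISITK",
    MotifClass.E2K8: "MEGISITK",
    MotifClass.K8_ONLY: "MGAISITK",
    MotifClass.TATB_LIKE: "MFDIGFSE",
    MotifClass.TATA_LIKE: "MGGISIWQ",
    MotifClass.UNCHARGED_OTHER: "MGGISIWA",
    MotifClass.OTHER_CHARGED: "MGEISITR",
}

#: classes whose definition requires a specific residue at position 8
_REQUIRES_R8 = {
    MotifClass.E3K8: "K",
    MotifClass.E2K8: "K",
    MotifClass.K8_ONLY: "K",
    MotifClass.TATB_LIKE: "E",
}


@dataclass(frozen=True)
class GroundTruth:
    record_id: str
    motif_class: MotifClass
    organism: str
    first8: str


@dataclass
class FamilySpec:
    """Parameters of one synthetic ortholog subfamily.

    ``per_position_conservation`` maps 1-based positions to the probability
    that a member carries the consensus residue there; position 3 of an
    E3K8 family switches to the Glu2 arrangement on failure, position 8
    falls back to Arg.  ``substitution_rate`` is the i.i.d. per-position
    substitution probability outside positions 1-8 (and outside positions
    with an explicit conservation entry).
    """

    n_sequences: int
    class_label: MotifClass
    length_range: tuple[int, int] = (50, 180)
    tm_start: int = 4
    tm_length: int = 18
    aph_length: int = 20
    per_position_conservation: dict[int, float] = field(default_factory=dict)
    substitution_rate: float = 0.0
    protect_motif: bool = True
    seed: int = 0
    id_prefix: str = "SYN"
    taxon_class: str = ""
    taxon_order: str = ""
    taxon_family: str = ""
    organism_format: str = ""
    annotated_name: str = "TatA"
    dual_paralog: bool = False
    template: str | None = None

    def __post_init__(self) -> None:
        if self.n_sequences < 0:
            raise ValueError("n_sequences must be >= 0")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid length_range")
        for pos, p in self.per_position_conservation.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"conservation probability at {pos} outside [0, 1]")
        required = _REQUIRES_R8.get(self.class_label)
        if required and self.per_position_conservation.get(8, 1.0) == 0.0:
            raise ValueError(
                f"contradictory spec: class {self.class_label.value} requires "
                f"{required} at position 8 but conservation{{8}} is 0"
            )
        if self.dual_paralog and self.class_label not in (
            MotifClass.E3K8,
            MotifClass.E2K8,
            MotifClass.K8_ONLY,
        ):
            raise ValueError("dual_paralog pairing requires a charged-motif class_label")


def make_template(length: int, rng: np.random.Generator, tm_start: int = 4,
                  tm_length: int = 18, aph_length: int = 20) -> str:
    """A full-length TatA-family-like backbone (positions 1-8 are overwritten
    later by the class motif)."""
    seq = ["M"]
    for pos in range(2, length + 1):
        if tm_start <= pos < tm_start + tm_length:
            seq.append(HYDROPHOBIC[rng.integers(len(HYDROPHOBIC))])
        elif pos < tm_start + tm_length + aph_length:
            # amphipathic: alternate hydrophobic and polar faces
            pool = HYDROPHOBIC if pos % 2 == 0 else POLAR
            seq.append(pool[rng.integers(len(pool))])
        else:
            seq.append(TAIL[rng.integers(len(TAIL))])
    return "".join(seq)


def _draw_first8(spec: FamilySpec, rng: np.random.Generator) -> tuple[str, MotifClass]:
    """Place the motif residues for one member; return (first8, realized label)."""
    cls = spec.class_label
    cons = spec.per_position_conservation
    first8 = list(_FIRST8[cls])
    label = cls
    if cls == MotifClass.E3K8 and 3 in cons:
        if rng.random() >= cons[3]:
            first8 = list(_FIRST8[MotifClass.E2K8])
            label = MotifClass.E2K8
    if cls in _REQUIRES_R8 and 8 in cons:
        if rng.random() >= cons[8]:
            if _REQUIRES_R8[cls] == "K":
                first8[7] = "R"
                label = MotifClass.OTHER_CHARGED
            else:  # acidic position 8: fall back to Asp, still TatB-type
                first8[7] = "D"
    return "".join(first8), label


def _substitute(res: str, rng: np.random.Generator) -> str:
    alt = RES20[rng.integers(len(RES20))]
    while alt == res:
        alt = RES20[rng.integers(len(RES20))]
    return alt


def generate_family(spec: FamilySpec) -> tuple[SequenceSet, list[GroundTruth], list[dict[str, str]]]:
    """Generate one subfamily (or paired subfamilies in dual-paralog mode).

    Returns the sequences, the per-record ground-truth labels (known from
    construction, including conservation-draw outcomes at positions 3 and
    8), and taxonomy TSV rows.  In ``dual_paralog`` mode every organism
    receives a charged-motif record and an uncharged TatA-type partner.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    template = spec.template or make_template(
        max(hi, 8), rng, spec.tm_start, spec.tm_length, spec.aph_length
    )
    records: list[ProteinRecord] = []
    truth: list[GroundTruth] = []
    tax_rows: list[dict[str, str]] = []
    taxonomy = Taxonomy(spec.taxon_class, spec.taxon_order, spec.taxon_family)
    org_fmt = spec.organism_format or (
        (spec.taxon_order or "Synthetica") + " sp. " + spec.id_prefix + "{i:03d}"
    )

    def build_member(rid: str, organism: str, cls_spec: FamilySpec, annotated: str):
        length = int(rng.integers(cls_spec.length_range[0], cls_spec.length_range[1] + 1))
        if cls_spec.class_label == MotifClass.TOO_SHORT:
            length = min(length, 7)
            seq = template[:length]
            label = MotifClass.TOO_SHORT
        else:
            length = max(length, 8)
            first8, label = _draw_first8(cls_spec, rng)
            body = list(template[:length])
            while len(body) < length:
                body.append(TAIL[rng.integers(len(TAIL))])
            body[:8] = list(first8)
            for pos in range(9, length + 1):
                p_cons = cls_spec.per_position_conservation.get(pos)
                if p_cons is not None:
                    if rng.random() >= p_cons:
                        body[pos - 1] = _substitute(body[pos - 1], rng)
                elif cls_spec.substitution_rate > 0 and rng.random() < cls_spec.substitution_rate:
                    body[pos - 1] = _substitute(body[pos - 1], rng)
            if not cls_spec.protect_motif and cls_spec.substitution_rate > 0:
                for pos in range(2, 9):
                    if rng.random() < cls_spec.substitution_rate:
                        body[pos - 1] = _substitute(body[pos - 1], rng)
            seq = "".join(body)
        rec = ProteinRecord(
            record_id=rid,
            sequence=seq,
            description=f"synthetic {annotated} [{organism}]",
            organism=organism,
            taxonomy=taxonomy,
            annotated_name=annotated,
        )
        records.append(rec)
        truth.append(GroundTruth(rid, label, organism, seq[:8]))
        tax_rows.append(
            {
                "accession": rid,
                "organism": organism,
                "class": spec.taxon_class,
                "order": spec.taxon_order,
                "family": spec.taxon_family,
                "annotated_name": annotated,
            }
        )

    from dataclasses import replace as _replace

    for i in range(1, spec.n_sequences + 1):
        organism = org_fmt.format(i=i)
        if spec.dual_paralog:
            build_member(f"{spec.id_prefix}_{i:04d}_1", organism, spec, spec.annotated_name)
            partner = _replace(
                spec,
                class_label=MotifClass.TATA_LIKE,
                per_position_conservation={},
                dual_paralog=False,
            )
            build_member(f"{spec.id_prefix}_{i:04d}_2", organism, partner, spec.annotated_name)
        else:
            build_member(f"{spec.id_prefix}_{i:04d}", organism, spec, spec.annotated_name)
    return SequenceSet(records=records, source_label=f"synthetic:{spec.id_prefix}"), truth, tax_rows


def generate_decoys(n: int, length: int = 100, seed: int = 0, initiator_met: bool = True) -> SequenceSet:
    """Unrelated decoy sequences with i.i.d. uniform residues.

    With ``initiator_met`` (default) position 1 is fixed to Met so decoys
    pass the incomplete-entry filter and are rejected on E-value alone.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(1, n + 1):
        seq = "".join(RES20[k] for k in rng.integers(len(RES20), size=length))
        if initiator_met:
            seq = "M" + seq[1:]
        records.append(
            ProteinRecord(
                record_id=f"DECOY_{i:04d}",
                sequence=seq,
                description="synthetic decoy (i.i.d. background)",
            )
        )
    return SequenceSet(records=records, source_label="synthetic:decoys")


@dataclass
class SurveyDatabase:
    """A complete synthetic database for an end-to-end survey run."""

    query: ProteinRecord
    db: SequenceSet
    truth: dict[str, MotifClass]
    tax_rows: list[dict[str, str]]
    family_sets: dict[str, SequenceSet]


def build_survey_database(seed: int = 1) -> SurveyDatabase:
    """Assemble the synthetic analogue of the database survey.

    All TatA-family subfamilies descend from one ancestral template (30%
    inter-family divergence, 10% within-family substitution noise outside
    the motif region), so every family member is detectably homologous to
    the TatE-type query while decoys are i.i.d. background.  Subfamily
    sizes follow the survey conditions: a 111-member TatE family with
    position-8 conservation 0.99 and a 72/28 Gly-Glu/Glu-Gly split at
    positions 2-3; 50 dual-paralog organisms in Vibrionales; TatA-, TatB-,
    K8-only and otherwise-charged subfamilies across several Orders; 20
    decoys; and 5 deliberately incomplete entries.
    """
    rng = np.random.default_rng(seed)
    ancestor = make_template(180, rng)
    q_body = list(ancestor[:67])
    q_body[:8] = list(_FIRST8[MotifClass.E3K8])
    query = ProteinRecord(
        record_id="QUERY_TATE",
        sequence="".join(q_body),
        description="synthetic TatE-type query (E3xxxxK8)",
        organism="Synthocoli enterica",
        annotated_name="TatE",
    )

    def fam_template(k: int, rate: float = 0.30) -> str:
        return mutate(ancestor, rate, seed * 1000 + k)

    specs = [
        # the query's own ortholog family diverges less from it than the
        # other subfamilies do
        FamilySpec(
            n_sequences=111, class_label=MotifClass.E3K8, length_range=(60, 70),
            per_position_conservation={8: 0.99, 3: 0.72}, substitution_rate=0.10,
            seed=seed * 1000 + 1, id_prefix="TATE", taxon_class="Gammaproteobacteria",
            taxon_order="Enterobacterales", taxon_family="Enterobacteriaceae",
            annotated_name="TatE", template=fam_template(1, 0.08),
        ),
        FamilySpec(
            n_sequences=50, class_label=MotifClass.E3K8, length_range=(63, 78),
            substitution_rate=0.10, seed=seed * 1000 + 2, id_prefix="VIB",
            taxon_class="Gammaproteobacteria", taxon_order="Vibrionales",
            annotated_name="TatA", dual_paralog=True, template=fam_template(2),
        ),
        FamilySpec(
            n_sequences=44, class_label=MotifClass.TATA_LIKE, length_range=(85, 95),
            substitution_rate=0.10, seed=seed * 1000 + 3, id_prefix="ENTA",
            taxon_class="Gammaproteobacteria", taxon_order="Enterobacterales",
            taxon_family="Enterobacteriaceae", annotated_name="TatA",
            template=fam_template(3),
        ),
        FamilySpec(
            n_sequences=40, class_label=MotifClass.TATA_LIKE, length_range=(70, 90),
            substitution_rate=0.10, seed=seed * 1000 + 4, id_prefix="PSEA",
            taxon_class="Gammaproteobacteria", taxon_order="Pseudomonadales",
            annotated_name="TatA", template=fam_template(4),
        ),
        FamilySpec(
            n_sequences=30, class_label=MotifClass.TATA_LIKE, length_range=(70, 90),
            substitution_rate=0.10, seed=seed * 1000 + 5, id_prefix="BURK",
            taxon_class="Betaproteobacteria", taxon_order="Burkholderiales",
            annotated_name="TatA", template=fam_template(5),
        ),
        FamilySpec(
            n_sequences=15, class_label=MotifClass.TATA_LIKE, length_range=(70, 90),
            substitution_rate=0.10, seed=seed * 1000 + 6, id_prefix="RHIZ",
            taxon_class="Alphaproteobacteria", taxon_order="Rhizobiales",
            annotated_name="TatA", template=fam_template(6),
        ),
        FamilySpec(
            n_sequences=20, class_label=MotifClass.TATB_LIKE, length_range=(100, 130),
            substitution_rate=0.10, seed=seed * 1000 + 7, id_prefix="TATB",
            taxon_class="Gammaproteobacteria", taxon_order="Enterobacterales",
            taxon_family="Enterobacteriaceae", annotated_name="TatB",
            template=fam_template(7),
        ),
        FamilySpec(
            n_sequences=12, class_label=MotifClass.K8_ONLY, length_range=(63, 80),
            substitution_rate=0.10, seed=seed * 1000 + 8, id_prefix="ALTE",
            taxon_class="Gammaproteobacteria", taxon_order="Alteromonadales",
            annotated_name="TatA", template=fam_template(8),
        ),
        FamilySpec(
            n_sequences=6, class_label=MotifClass.OTHER_CHARGED, length_range=(70, 90),
            substitution_rate=0.10, seed=seed * 1000 + 9, id_prefix="RHOD",
            taxon_class="Alphaproteobacteria", taxon_order="Rhodobacterales",
            annotated_name="TatA", template=fam_template(9),
        ),
    ]
    records: list[ProteinRecord] = []
    truth: dict[str, MotifClass] = {}
    tax_rows: list[dict[str, str]] = []
    family_sets: dict[str, SequenceSet] = {}
    for spec in specs:
        seqs, gts, rows = generate_family(spec)
        records.extend(seqs)
        truth.update({gt.record_id: gt.motif_class for gt in gts})
        tax_rows.extend(rows)
        family_sets[spec.id_prefix] = seqs
    records.extend(generate_decoys(20, length=100, seed=seed * 1000 + 10))
    # deliberately incomplete entries that the filter must remove
    frag_rng = np.random.default_rng(seed * 1000 + 11)
    for i, flaw in enumerate(["partial", "short", "no_met", "xrun", "partial"], start=1):
        body = mutate(ancestor[:70], 0.1, seed * 1000 + 11 + i)
        if flaw == "partial":
            rec = ProteinRecord(f"FRAG_{i:02d}", body, description="hypothetical protein, partial")
        elif flaw == "short":
            rec = ProteinRecord(f"FRAG_{i:02d}", body[:20], description="fragment")
        elif flaw == "no_met":
            rec = ProteinRecord(f"FRAG_{i:02d}", "G" + body[1:], description="truncated entry")
        else:
            nx = list(body)
            for k in frag_rng.integers(8, len(nx), size=12):
                nx[int(k)] = "X"
            rec = ProteinRecord(f"FRAG_{i:02d}", "".join(nx), description="low quality entry")
        records.append(rec)
    return SurveyDatabase(
        query=query,
        db=SequenceSet(records=records, source_label="synthetic survey database"),
        truth=truth,
        tax_rows=tax_rows,
        family_sets=family_sets,
    )


def vibrionales_exemplar_octet(seed: int = 1) -> tuple[SequenceSet, SequenceSet]:
    """Synthetic stand-ins for the eight paired Vibrionales TatA_1/TatA_2
    exemplars: eight charged TatA_1-like sequences of which exactly seven
    carry the E3xxxxK8 motif and one only the Lys8, spanning 63-78 residues
    with both extremes realized, plus their eight uncharged TatA_2-like
    partners.

    These are generated stand-ins embodying the documented composition of
    that exemplar set, not the database records themselves.
    """
    rng = np.random.default_rng(seed)
    template = make_template(80, rng)
    lengths = [63, 65, 67, 69, 71, 73, 75, 78]
    tata1, tata2 = [], []
    for i, length in enumerate(lengths, start=1):
        organism = f"Synthophotobacterium sp. {i:02d}"
        cls = MotifClass.E3K8 if i <= 7 else MotifClass.K8_ONLY
        body = list(mutate(template[:length], 0.08, seed * 100 + i))
        body[:8] = list(_FIRST8[cls])
        tata1.append(
            ProteinRecord(
                record_id=f"SYNV1_{i:02d}", sequence="".join(body),
                description=f"synthetic TatA_1 stand-in [{organism}]",
                organism=organism,
                taxonomy=Taxonomy("Gammaproteobacteria", "Vibrionales", ""),
                annotated_name="TatA",
            )
        )
        body2 = list(mutate(template[:56], 0.08, seed * 100 + 50 + i))
        body2[:8] = list(_FIRST8[MotifClass.TATA_LIKE])
        tata2.append(
            ProteinRecord(
                record_id=f"SYNV2_{i:02d}", sequence="".join(body2),
                description=f"synthetic TatA_2 stand-in [{organism}]",
                organism=organism,
                taxonomy=Taxonomy("Gammaproteobacteria", "Vibrionales", ""),
                annotated_name="TatA",
            )
        )
    return (
        SequenceSet(records=tata1, source_label="synthetic TatA_1 octet"),
        SequenceSet(records=tata2, source_label="synthetic TatA_2 octet"),
    )


def mutate(seq: str, rate: float, seed: int, protect_first: int = 8) -> str:
    """Substitute positions beyond ``protect_first`` i.i.d. at ``rate``."""
    rng = np.random.default_rng(seed)
    out = list(seq)
    for pos in range(protect_first, len(out)):
        if rng.random() < rate:
            out[pos] = _substitute(out[pos], rng)
    return "".join(out)
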
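"""Classification of TatA-family proteins by N-terminal charge architecture.

TatE-type proteins carry a glutamate at position 3 (or 2) together with a
lysine at position 8; TatB-type proteins carry an acidic residue at
position 8; TatA-type proteins are uncharged in the N-terminus with a polar
residue (typically Gln) at position 8.  Positions are 1-based counting the
initiator methionine as position 1 -- the convention under which the
Glu3/Lys8 indices match the E. coli TatE primary sequence.

"Charged" means D/E (acidic) or K/R (basic); histidine is treated as
polar-uncharged.  Classification reads only the first eight residues.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Mapping

ACIDIC = frozenset("DE")
BASIC = frozenset("KR")
CHARGED = ACIDIC | BASIC
POLAR_UNCHARGED = frozenset("QHNST")


class MotifClass(str, enum.Enum):
    """N-terminal charge-architecture categories.

    E3K8/E2K8 are the TatE-defining motifs (ExxxxK anchored at position 3
    or 2); K8_ONLY has the lysine without the glutamate; TATB_LIKE has an
    acidic residue at position 8; TATA_LIKE is uncharged with a polar
    residue 8; UNCHARGED_OTHER is uncharged with a non-polar residue 8;
    OTHER_CHARGED covers any remaining charged pattern in positions 2-8.
    """

    E3K8 = "E3K8"
    E2K8 = "E2K8"
    K8_ONLY = "K8_ONLY"
    TATB_LIKE = "TATB_LIKE"
    TATA_LIKE = "TATA_LIKE"
    UNCHARGED_OTHER = "UNCHARGED_OTHER"
    OTHER_CHARGED = "OTHER_CHARGED"
    TOO_SHORT = "TOO_SHORT"


#: classes whose N-terminus carries the TatE-type charge pattern
CHARGED_MOTIF_CLASSES = frozenset({MotifClass.E3K8, MotifClass.E2K8, MotifClass.K8_ONLY})
#: classes with no charged residue in positions 2-8 (TatA-type state)
UNCHARGED_CLASSES = frozenset({MotifClass.TATA_LIKE, MotifClass.UNCHARGED_OTHER})


@dataclass(frozen=True)
class ChargeProfile:
    """Per-position charge evidence in the N-terminal window.

    ``charges`` lists (1-based position, residue, polarity) for every D/E/K/R
    in positions 2-8; position 1 (the initiator Met by convention) is never
    counted as charge evidence.  ``residue8`` is empty for sequences shorter
    than eight residues.
    """

    window: str
    charges: tuple[tuple[int, str, str], ...]
    residue8: str


def charge_profile(seq, window_size: int = 10) -> ChargeProfile:
    """Scan the first ``window_size`` residues for charged positions 2-8."""
    s = seq if isinstance(seq, str) else seq.sequence
    window = s[:window_size]
    charges = []
    for pos in range(2, min(len(s), 8) + 1):
        res = s[pos - 1]
        if res in ACIDIC:
            charges.append((pos, res, "acidic"))
        elif res in BASIC:
            charges.append((pos, res, "basic"))
    residue8 = s[7] if len(s) >= 8 else ""
    return ChargeProfile(window=window, charges=tuple(charges), residue8=residue8)


@dataclass(frozen=True)
class Classification:
    """A motif class plus the descriptive Gly/Glu order at positions 2-3."""

    motif_class: MotifClass
    gly_glu_order: str  # "Gly-Glu", "Glu-Gly" or "none"
    profile: ChargeProfile


def classify(seq) -> MotifClass:
    """Assign exactly one motif class from the first eight residues.

    Decision order: TOO_SHORT; E3K8 (checked before E2K8, the majority
    pattern); E2K8; K8_ONLY; TATB_LIKE (acidic residue 8); uncharged 2-8
    split into TATA_LIKE (polar residue 8) vs UNCHARGED_OTHER; anything
    else charged in 2-8 is OTHER_CHARGED.
    """
    s = seq if isinstance(seq, str) else seq.sequence
    if len(s) < 8:
        return MotifClass.TOO_SHORT
    r8 = s[7]
    if s[2] == "E" and r8 == "K":
        return MotifClass.E3K8
    if s[1] == "E" and r8 == "K":
        return MotifClass.E2K8
    if r8 == "K":
        return MotifClass.K8_ONLY
    if r8 in ACIDIC:
        return MotifClass.TATB_LIKE
    if not any(c in CHARGED for c in s[1:8]):
        return MotifClass.TATA_LIKE if r8 in POLAR_UNCHARGED else MotifClass.UNCHARGED_OTHER
    return MotifClass.OTHER_CHARGED


def classify_full(seq, window_size: int = 10) -> Classification:
    """Classify and record the Gly-Glu / Glu-Gly order for the TatE motifs."""
    s = seq if isinstance(seq, str) else seq.sequence
    cls = classify(s)
    order = "none"
    if cls in (MotifClass.E3K8, MotifClass.E2K8):
        if s[1:3] == "GE":
            order = "Gly-Glu"
        elif s[1:3] == "EG":
            order = "Glu-Gly"
    return Classification(motif_class=cls, gly_glu_order=order, profile=charge_profile(s, window_size))


def classify_set(seqs) -> tuple[dict[str, MotifClass], Counter]:
    """Classify every record; the tallies always sum to the set size."""
    classes = {rec.record_id: classify(rec) for rec in seqs}
    tallies = Counter(classes.values())
    return classes, tallies


def tallies_as_dict(tallies: Mapping[MotifClass, int]) -> dict[str, int]:
    """Tallies keyed by class name, all classes present, fixed order."""
    return {cls.value: int(tallies.get(cls, 0)) for cls in MotifClass}
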
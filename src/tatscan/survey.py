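"""Taxonomic aggregation of motif classes and dual-paralog genome detection.

The survey reproduces the structure of a per-Order tally table: for every
(Class, Order) pair, the number of screened proteins and how many of them
carry an N-terminal charge pattern (E3K8, E2K8 or K8_ONLY).  A
"dual-paralog" organism is one encoding both a charged-motif TatA-family
paralog and an uncharged TatA-type one -- the TatA_1/TatA_2 pattern that
marks a genome as carrying a distinct TatE-type protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from tatscan.motif import CHARGED_MOTIF_CLASSES, UNCHARGED_CLASSES, MotifClass
from tatscan.records import SequenceSet

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class SurveyRow:
    class_: str
    order: str
    total: int
    n_charged: int


@dataclass(frozen=True)
class DualParalogOrganism:
    organism: str
    charged: tuple[tuple[str, MotifClass], ...]  # (record_id, class)
    uncharged: tuple[tuple[str, MotifClass], ...]


@dataclass
class SurveyReport:
    rows: list[SurveyRow] = field(default_factory=list)
    grand_total: int = 0
    grand_charged: int = 0
    dual_paralog_organisms: list[DualParalogOrganism] = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = ["class\torder\ttotal\tn_charged"]
        for r in self.rows:
            lines.append(f"{r.class_}\t{r.order}\t{r.total}\t{r.n_charged}")
        lines.append(f"all\tall\t{self.grand_total}\t{self.grand_charged}")
        return "\n".join(lines) + "\n"

    def dual_paralogs_tsv(self) -> str:
        lines = ["organism\tcharged_record\tcharged_class\tuncharged_record\tuncharged_class"]
        for org in self.dual_paralog_organisms:
            cid, ccls = org.charged[0]
            uid, ucls = org.uncharged[0]
            lines.append(f"{org.organism}\t{cid}\t{ccls.value}\t{uid}\t{ucls.value}")
        return "\n".join(lines) + "\n"


def tabulate(seqs: SequenceSet, classes: Mapping[str, MotifClass]) -> SurveyReport:
    """Aggregate classified records by (Class, Order).

    Records with an empty Class or Order land in the catch-all
    "unassigned" row.  Row order: Class alphabetical, then Order by
    descending total, then alphabetical.  Dual-paralog organisms are
    attached to the report.
    """
    cells: dict[tuple[str, str], list[MotifClass]] = {}
    for rec in seqs:
        cls = classes.get(rec.record_id)
        if cls is None:
            continue
        taxon_class = rec.taxonomy.class_ or UNASSIGNED
        taxon_order = rec.taxonomy.order or UNASSIGNED
        cells.setdefault((taxon_class, taxon_order), []).append(cls)
    rows = [
        SurveyRow(
            class_=tc,
            order=to,
            total=len(motifs),
            n_charged=sum(1 for m in motifs if m in CHARGED_MOTIF_CLASSES),
        )
        for (tc, to), motifs in cells.items()
    ]
    rows.sort(key=lambda r: (r.class_, -r.total, r.order))
    report = SurveyReport(
        rows=rows,
        grand_total=sum(r.total for r in rows),
        grand_charged=sum(r.n_charged for r in rows),
        dual_paralog_organisms=find_dual_paralogs(seqs, classes),
    )
    return report


def find_dual_paralogs(
    seqs: SequenceSet, classes: Mapping[str, MotifClass]
) -> list[DualParalogOrganism]:
    """Organisms with >= 1 charged-motif record and >= 1 uncharged record.

    Organism identity is string equality of the organism field; records
    with an empty organism never participate.  Output is sorted by
    organism name and duplication-free regardless of record order.
    """
    by_org: dict[str, tuple[list, list]] = {}
    for rec in seqs:
        cls = classes.get(rec.record_id)
        if cls is None or not rec.organism:
            continue
        charged, uncharged = by_org.setdefault(rec.organism, ([], []))
        if cls in CHARGED_MOTIF_CLASSES:
            charged.append((rec.record_id, cls))
        elif cls in UNCHARGED_CLASSES:
            uncharged.append((rec.record_id, cls))
    out = []
    for org in sorted(by_org):
        charged, uncharged = by_org[org]
        if charged and uncharged:
            out.append(
                DualParalogOrganism(
                    organism=org,
                    charged=tuple(sorted(charged)),
                    uncharged=tuple(sorted(uncharged)),
                )
            )
    return out
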
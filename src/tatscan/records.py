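"""Protein records, FASTA I/O and the taxonomy table.

A :class:`ProteinRecord` is one database entry: a validated amino-acid
sequence plus the annotation needed by the survey (accession, organism,
Class/Order/Family labels, and the database's own name for the protein,
e.g. "TatA" or "TatE").  Collections are :class:`SequenceSet`, which keeps
file order so every downstream stage is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, NamedTuple

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids plus X for undetermined residues.
ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input."""


class SequenceValidationError(ValueError):
    """Raised when a sequence contains characters outside the residue alphabet."""


class TaxonomyError(ValueError):
    """Raised for malformed taxonomy tables."""


class Taxonomy(NamedTuple):
    """Ordered taxonomic labels; any may be empty."""

    class_: str = ""
    order: str = ""
    family: str = ""


class TaxonomyEntry(NamedTuple):
    """One row of the taxonomy/annotation table."""

    organism: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    annotated_name: str = ""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its annotation.

    ``accession`` defaults to ``record_id`` (the first whitespace-delimited
    FASTA header token), which is correct for RefSeq/UniProt-style headers.
    """

    record_id: str
    sequence: str
    description: str = ""
    accession: str = ""
    organism: str = ""
    taxonomy: Taxonomy = Taxonomy()
    annotated_name: str = ""

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        if len(self.sequence) < 1:
            raise SequenceValidationError(f"record {self.record_id!r}: empty sequence")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in ALPHABET:
                raise SequenceValidationError(
                    f"record {self.record_id!r}: illegal residue {ch!r} at position {pos}"
                )
        if not self.accession:
            object.__setattr__(self, "accession", self.record_id)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SequenceSet:
    """An ordered collection of records; iteration follows input order."""

    records: list[ProteinRecord] = field(default_factory=list)
    source_label: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen:
                raise ValueError(f"duplicate record_id {rec.record_id!r} in sequence set")
            seen.add(rec.record_id)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, key: int | str) -> ProteinRecord:
        if isinstance(key, str):
            for rec in self.records:
                if rec.record_id == key:
                    return rec
            raise KeyError(key)
        return self.records[key]

    @property
    def ids(self) -> list[str]:
        return [rec.record_id for rec in self.records]

    def total_residues(self) -> int:
        return sum(len(rec) for rec in self.records)


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a protein FASTA file into a :class:`SequenceSet`.

    The header token before the first whitespace becomes ``record_id``; the
    remainder of the header line becomes ``description``.  Sequences are
    upper-cased and validated against the 21-letter alphabet.  A sequence
    line appearing before any ``>`` header is a :class:`FastaParseError`
    naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before any FASTA header"
                )
            break
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(
                record_id=entry.id,
                description=entry.description[len(entry.id):].strip(),
                sequence=str(entry.seq).upper(),
            )
        )
    return SequenceSet(records=records, source_label=str(path))


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 60) -> None:
    """Write records in input order, wrapping sequence lines at ``width``."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in seqs:
            header = rec.record_id if not rec.description else f"{rec.record_id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


_COLUMN_ALIASES = {
    "accession": "accession",
    "organism": "organism",
    "class": "class_",
    "order": "order",
    "family": "family",
    "annotated_name": "annotated_name",
}


def read_taxonomy(path: str | Path) -> dict[str, TaxonomyEntry]:
    """Read the taxonomy/annotation TSV into a mapping accession -> entry.

    The file must be tab-separated with a header row naming at least
    ``accession`` and ``order`` (case-insensitive).  Missing optional columns
    yield empty strings; duplicate accessions are an error listing them.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    for mandatory in ("accession", "order"):
        if mandatory not in df.columns:
            raise TaxonomyError(f"{path}: missing mandatory column {mandatory!r}")
    dup = df["accession"][df["accession"].duplicated()].tolist()
    if dup:
        raise TaxonomyError(f"{path}: duplicate accession rows: {sorted(set(dup))}")
    mapping: dict[str, TaxonomyEntry] = {}
    for d in df.to_dict("records"):
        mapping[d["accession"]] = TaxonomyEntry(
            organism=d.get("organism", ""),
            class_=d.get("class", ""),
            order=d.get("order", ""),
            family=d.get("family", ""),
            annotated_name=d.get("annotated_name", ""),
        )
    return mapping


def attach_taxonomy(seqs: SequenceSet, tax: Mapping[str, TaxonomyEntry]) -> SequenceSet:
    """Return a new SequenceSet with taxonomy fields filled from the mapping.

    Records whose accession is absent from the mapping are passed through
    untouched; the number of unmatched records is logged, not raised.
    """
    out: list[ProteinRecord] = []
    unmatched = 0
    for rec in seqs:
        entry = tax.get(rec.accession)
        if entry is None:
            unmatched += 1
            out.append(rec)
            continue
        out.append(
            replace(
                rec,
                organism=entry.organism,
                taxonomy=Taxonomy(entry.class_, entry.order, entry.family),
                annotated_name=entry.annotated_name,
            )
        )
    if unmatched:
        logger.info("attach_taxonomy: %d of %d records had no taxonomy entry", unmatched, len(seqs))
    return SequenceSet(records=out, source_label=seqs.source_label)


def write_taxonomy(rows: list[dict[str, str]], path: str | Path) -> None:
    """Write a taxonomy TSV with the canonical column order."""
    cols = ["accession", "organism", "class", "order", "family", "annotated_name"]
    df = pd.DataFrame(rows, columns=cols).fillna("")
    df.to_csv(path, sep="\t", index=False)
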
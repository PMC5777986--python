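"""Database screening: local alignment of a query against a sequence set.

Mirrors a BLASTP-style survey: incomplete entries are removed first, every
remaining record is aligned locally against the query, and hits are the
records whose Karlin-Altschul E-value is at or below the cutoff (default
1e-3).  The search-space length n is the total residue count of the
filtered database.

"Incomplete" is operationalized as the union of cheap proxies for partial
database entries: shorter than ``min_length``, more than
``exclude_x_fraction`` undetermined (X) residues, missing the initiator
methionine, or a definition line containing the token "partial".
"""

from __future__ import annotations

from dataclasses import dataclass, field

from tatscan.alignment import AlignmentResult, ScoringScheme, align_local
from tatscan.records import ProteinRecord, SequenceSet


@dataclass(frozen=True)
class ScreenConfig:
    e_cutoff: float = 1e-3
    min_length: int = 40
    exclude_x_fraction: float = 0.05
    require_initiator_met: bool = True

    def __post_init__(self) -> None:
        if self.e_cutoff <= 0:
            raise ValueError("e_cutoff must be positive")
        if not 0 <= self.exclude_x_fraction <= 1:
            raise ValueError("exclude_x_fraction must be in [0, 1]")


@dataclass
class ScreenResult:
    """Hits sorted by ascending E-value (ties by record_id) plus the tally.

    n_input = n_removed_incomplete + n_hits + n_above_cutoff.
    """

    hits: list[tuple[ProteinRecord, AlignmentResult]] = field(default_factory=list)
    n_input: int = 0
    n_removed_incomplete: int = 0
    n_above_cutoff: int = 0

    @property
    def n_hits(self) -> int:
        return len(self.hits)

    def tally(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_removed_incomplete": self.n_removed_incomplete,
            "n_hits": self.n_hits,
            "n_above_cutoff": self.n_above_cutoff,
        }

    def hit_set(self) -> SequenceSet:
        return SequenceSet(records=[rec for rec, _ in self.hits], source_label="screen hits")


def is_incomplete(rec: ProteinRecord, cfg: ScreenConfig) -> bool:
    if len(rec) < cfg.min_length:
        return True
    if len(rec) and rec.sequence.count("X") / len(rec) > cfg.exclude_x_fraction:
        return True
    if cfg.require_initiator_met and not rec.sequence.startswith("M"):
        return True
    if "partial" in rec.description.lower():
        return True
    return False


def filter_incomplete(seqs: SequenceSet, cfg: ScreenConfig | None = None) -> tuple[SequenceSet, SequenceSet]:
    """Split a set into (kept, removed); the two partitions are disjoint and
    together reproduce the input."""
    cfg = cfg or ScreenConfig()
    kept, removed = [], []
    for rec in seqs:
        (removed if is_incomplete(rec, cfg) else kept).append(rec)
    return (
        SequenceSet(records=kept, source_label=seqs.source_label),
        SequenceSet(records=removed, source_label=f"{seqs.source_label} (removed)"),
    )


def screen(
    query: ProteinRecord,
    db: SequenceSet,
    cfg: ScreenConfig | None = None,
    scheme: ScoringScheme | None = None,
) -> ScreenResult:
    """Screen the database with the query; keep records with E <= cutoff.

    An empty database after filtering yields a zero-hit result, not an
    error.  Identical inputs and configuration produce byte-identical
    sorted hit lists.
    """
    cfg = cfg or ScreenConfig()
    scheme = scheme or ScoringScheme()
    kept, removed = filter_incomplete(db, cfg)
    n_search = kept.total_residues()
    hits: list[tuple[ProteinRecord, AlignmentResult]] = []
    n_above = 0
    for rec in kept:
        res = align_local(query, rec, scheme, search_space=max(n_search, 1))
        if res.e_value <= cfg.e_cutoff:
            hits.append((rec, res))
        else:
            n_above += 1
    hits.sort(key=lambda pair: (pair[1].e_value, pair[0].record_id))
    return ScreenResult(
        hits=hits,
        n_input=len(db),
        n_removed_incomplete=len(removed),
        n_above_cutoff=n_above,
    )
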
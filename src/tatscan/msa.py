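"""Progressive multiple sequence alignment and consensus/conservation models.

The aligner is Clustal-style: a pairwise identity distance matrix feeds a
UPGMA guide tree, and profiles are merged bottom-up with a profile-profile
Needleman-Wunsch using frequency-weighted sum-of-pairs substitution scores
and affine gap costs.  Ties in the guide tree are broken by lexicographic
record id, and traceback ties prefer the diagonal, so the output depends
only on the set of sequences, not their input order.

The consensus model reports, per column, residue frequencies, the consensus
residue (most frequent non-gap residue, ties alphabetical), the
conservation (fraction of non-gap symbols equal to the consensus residue)
and the information content in bits, log2(20) minus the Shannon entropy of
the standard-residue distribution.  Gaps and X are excluded from
conservation and information, which are residue-space statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from tatscan.alignment import ScoringScheme, align_global
from tatscan.records import SequenceSet

_RES20 = "ACDEFGHIKLMNPQRSTVWY"
_SYMBOLS = _RES20 + "X-"
_SYM_INDEX = {c: i for i, c in enumerate(_SYMBOLS)}
LOG2_20 = math.log2(20.0)


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows; degapping row i recovers input sequence i."""

    record_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.record_ids) != len(self.rows):
            raise ValueError("record_ids and rows must have equal length")
        if self.rows:
            ncol = len(self.rows[0])
            if any(len(r) != ncol for r in self.rows):
                raise ValueError("all alignment rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def row_for(self, record_id: str) -> str:
        return self.rows[self.record_ids.index(record_id)]


def _identity_distance(seqs: list, scheme: ScoringScheme) -> np.ndarray:
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = align_global(seqs[i], seqs[j], scheme)
            frac = res.n_identical / res.aligned_columns if res.aligned_columns else 0.0
            dist[i, j] = dist[j, i] = 1.0 - frac
    return dist


def _profile(rows: list[str]) -> np.ndarray:
    """Column frequency matrix (n_columns x 22) over residues, X and gap."""
    ncol = len(rows[0])
    prof = np.zeros((ncol, len(_SYMBOLS)))
    for row in rows:
        for j, c in enumerate(row):
            prof[j, _SYM_INDEX[c]] += 1.0
    return prof / len(rows)


def _profile_align(rows_a: list[str], rows_b: list[str], scheme: ScoringScheme) -> tuple[list[str], list[str]]:
    """Align two profiles with affine gaps; return the two padded row groups."""
    pa, pb = _profile(rows_a), _profile(rows_b)
    # substitution block: residues + X (gap frequencies contribute zero)
    S = np.asarray(scheme.matrix, dtype=float)  # 21x21, RESIDUES order A..Y,X
    # reorder to _SYMBOLS residue order (same letters, different order)
    from tatscan.alignment import RESIDUES as _ALN_RES

    perm = [_ALN_RES.index(c) for c in _RES20 + "X"]
    S = S[np.ix_(perm, perm)]
    col_scores = pa[:, :21] @ S @ pb[:, :21].T  # (la x lb)
    la, lb = col_scores.shape
    go, ge = float(scheme.gap_open), float(scheme.gap_extend)
    NEG = -1e18
    M = np.full((la + 1, lb + 1), NEG)
    Ix = np.full((la + 1, lb + 1), NEG)
    Iy = np.full((la + 1, lb + 1), NEG)
    ptr_m = np.zeros((la + 1, lb + 1), dtype=np.int8)  # source state of M: 0=M,1=Ix,2=Iy
    ptr_x = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptr_y = np.zeros((la + 1, lb + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        Ix[i, 0] = -go - ge * i
        ptr_x[i, 0] = 1 if i > 1 else 0
    for j in range(1, lb + 1):
        Iy[0, j] = -go - ge * j
        ptr_y[0, j] = 2 if j > 1 else 0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            # M: diagonal; prefer M > Ix > Iy sources on ties
            cands = (M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            bi = 0
            if cands[1] > cands[bi]:
                bi = 1
            if cands[2] > cands[bi]:
                bi = 2
            M[i, j] = col_scores[i - 1, j - 1] + cands[bi]
            ptr_m[i, j] = bi
            # Ix: gap in B, consume A column
            cx = (M[i - 1, j] - go - ge, Ix[i - 1, j] - ge, Iy[i - 1, j] - go - ge)
            bi = 0
            if cx[1] > cx[bi]:
                bi = 1
            if cx[2] > cx[bi]:
                bi = 2
            Ix[i, j] = cx[bi]
            ptr_x[i, j] = bi
            # Iy: gap in A, consume B column
            cy = (M[i, j - 1] - go - ge, Ix[i, j - 1] - go - ge, Iy[i, j - 1] - ge)
            bi = 0
            if cy[1] > cy[bi]:
                bi = 1
            if cy[2] > cy[bi]:
                bi = 2
            Iy[i, j] = cy[bi]
            ptr_y[i, j] = bi
    finals = (M[la, lb], Ix[la, lb], Iy[la, lb])
    state = 0
    if finals[1] > finals[state]:
        state = 1
    if finals[2] > finals[state]:
        state = 2
    i, j = la, lb
    moves: list[tuple[int, int]] = []
    while i > 0 or j > 0:
        if state == 0:
            moves.append((1, 1))
            state = ptr_m[i, j]
            i, j = i - 1, j - 1
        elif state == 1:
            moves.append((1, 0))
            state = ptr_x[i, j]
            i -= 1
        else:
            moves.append((0, 1))
            state = ptr_y[i, j]
            j -= 1
    moves.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for da, db in moves:
        for k, row in enumerate(rows_a):
            out_a[k] += row[ia] if da else "-"
        for k, row in enumerate(rows_b):
            out_b[k] += row[ib] if db else "-"
        ia += da
        ib += db
    return out_a, out_b


def align_progressive(seqs: SequenceSet, scheme: ScoringScheme | None = None) -> MultipleAlignment:
    """Progressive MSA over a sequence set (>= 2 sequences).

    Deterministic for a given set of records regardless of input order;
    output rows are returned in input order.
    """
    if len(seqs) < 2:
        raise ValueError("progressive alignment requires at least 2 sequences")
    scheme = scheme or ScoringScheme()
    recs = list(seqs)
    ids = [r.record_id for r in recs]
    dist = _identity_distance(recs, scheme)
    n = len(recs)
    pair_dist = {
        frozenset((i, j)): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    merges = _upgma_merges(ids, n, pair_dist)
    # materialize alignments bottom-up
    aligned: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [recs[i].sequence]) for i in range(n)
    }
    nxt = n
    for a, b in merges:
        ids_a, rows_a = aligned.pop(a)
        ids_b, rows_b = aligned.pop(b)
        # deterministic left/right: group containing the smallest id goes left
        if min(ids_b) < min(ids_a):
            ids_a, rows_a, ids_b, rows_b = ids_b, rows_b, ids_a, rows_a
        new_a, new_b = _profile_align(rows_a, rows_b, scheme)
        aligned[nxt] = (ids_a + ids_b, new_a + new_b)
        nxt += 1
    (final_ids, final_rows) = aligned[nxt - 1]
    order = {rid: k for k, rid in enumerate(final_ids)}
    rows_in_input_order = [final_rows[order[rid]] for rid in ids]
    return MultipleAlignment(record_ids=ids, rows=rows_in_input_order)


def _upgma_merges(
    ids: list[str], n: int, d: dict[frozenset[int], float]
) -> list[tuple[int, int]]:
    """UPGMA merge order (average linkage) over a leaf pair-distance map.

    Clusters are numbered 0..n-1 for leaves, then n, n+1, ... in merge
    order.  Ties on distance are broken by the lexicographic smallest
    member id of the joined pair, making the tree permutation invariant.
    """
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    minid: dict[int, str] = {i: ids[i] for i in range(n)}
    active = set(range(n))
    merges: list[tuple[int, int]] = []
    nxt = n
    while len(active) > 1:
        best = None
        for pair in list(d.keys()):
            a, b = tuple(pair)
            if a not in active or b not in active:
                continue
            lo, hi = sorted((a, b), key=lambda c: minid[c])
            key = (d[pair], minid[lo], minid[hi])
            if best is None or key < best[0]:
                best = (key, lo, hi)
        _, a, b = best
        for c in active - {a, b}:
            va = d[frozenset((a, c))]
            vb = d[frozenset((b, c))]
            d[frozenset((nxt, c))] = (len(members[a]) * va + len(members[b]) * vb) / (
                len(members[a]) + len(members[b])
            )
        members[nxt] = members[a] + members[b]
        minid[nxt] = min(minid[a], minid[b])
        active -= {a, b}
        active.add(nxt)
        merges.append((a, b))
        nxt += 1
    return merges


@dataclass(frozen=True)
class ColumnModel:
    frequencies: dict[str, float]  # over residues, X and '-' -- sums to 1
    consensus_residue: str
    conservation: float
    information_content: float


@dataclass
class ConsensusModel:
    columns: list[ColumnModel]
    n_sequences: int

    @property
    def consensus(self) -> str:
        return "".join(c.consensus_residue for c in self.columns)

    def to_tsv(self) -> str:
        lines = ["column\tconsensus\tconservation\tinformation_bits"]
        for k, col in enumerate(self.columns, start=1):
            lines.append(
                f"{k}\t{col.consensus_residue}\t{col.conservation:.6f}\t{col.information_content:.6f}"
            )
        return "\n".join(lines) + "\n"


def consensus(msa: MultipleAlignment) -> ConsensusModel:
    """Per-column consensus/conservation/information over an alignment.

    All-gap columns yield consensus '-', conservation 0 and information 0.
    """
    if msa.n_sequences == 0:
        raise ValueError("empty alignment")
    cols: list[ColumnModel] = []
    for j in range(msa.n_columns):
        symbols = [row[j] for row in msa.rows]
        freq = {s: symbols.count(s) / len(symbols) for s in sorted(set(symbols))}
        residues = [s for s in symbols if s in _RES20]
        nongap = [s for s in symbols if s != "-"]
        if not nongap:
            cols.append(ColumnModel(freq, "-", 0.0, 0.0))
            continue
        counts = {r: residues.count(r) for r in sorted(set(residues))}
        if counts:
            cons = max(sorted(counts), key=lambda r: counts[r])  # ties alphabetical
        else:
            cons = "X"  # only X among non-gap symbols
        conservation = (counts.get(cons, 0) if counts else nongap.count("X")) / len(nongap)
        if residues:
            probs = np.array([c / len(residues) for c in counts.values()])
            entropy = float(-(probs * np.log2(probs)).sum())
            info = max(LOG2_20 - entropy, 0.0)
        else:
            info = 0.0
        cols.append(ColumnModel(freq, cons, conservation, info))
    return ConsensusModel(columns=cols, n_sequences=msa.n_sequences)


def logo_matrix(model: ConsensusModel) -> list[list[tuple[str, float]]]:
    """Per-column (residue, height) entries with height = frequency x information.

    Frequencies are taken over standard residues only, so the heights of a
    column sum to its information content -- the logo convention.
    """
    out: list[list[tuple[str, float]]] = []
    for col in model.columns:
        res_freq = {r: f for r, f in col.frequencies.items() if r in _RES20}
        total = sum(res_freq.values())
        entries: list[tuple[str, float]] = []
        if total > 0:
            for r in sorted(res_freq):
                entries.append((r, (res_freq[r] / total) * col.information_content))
        out.append(entries)
    return out


def logo_matrix_tsv(model: ConsensusModel) -> str:
    lines = ["column\tresidue\theight"]
    for k, entries in enumerate(logo_matrix(model), start=1):
        for r, h in entries:
            lines.append(f"{k}\t{r}\t{h:.6f}")
    return "\n".join(lines) + "\n"


def reference_coordinates(msa: MultipleAlignment, reference_id: str) -> list[int | None]:
    """Map each alignment column to a 1-based residue position of the
    reference record, or None where the reference row has a gap.

    Anchors consensus-column claims (e.g. "position 8") to a designated
    reference sequence.
    """
    row = msa.row_for(reference_id)
    out: list[int | None] = []
    pos = 0
    for c in row:
        if c == "-":
            out.append(None)
        else:
            pos += 1
            out.append(pos)
    return out


def column_for_reference_position(msa: MultipleAlignment, reference_id: str, position: int) -> int:
    """0-based alignment column holding the reference's 1-based position."""
    coords = reference_coordinates(msa, reference_id)
    return coords.index(position)


def write_aligned_fasta(msa: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(msa.record_ids, msa.rows):
            fh.write(f">{rid}\n{row}\n")
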
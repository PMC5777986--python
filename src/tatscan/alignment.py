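"""Pairwise protein alignment with affine gaps and Karlin-Altschul statistics.

Implements global (Needleman-Wunsch/Gotoh) and local (Smith-Waterman)
alignment under a substitution matrix with affine gap costs: a gap of
length ``L`` costs ``gap_open + L * gap_extend``, the NCBI "existence 11,
extension 1" convention.  Raw scores are converted to bit scores and
E-values with the Karlin-Altschul formula

    bits = (lambda * S - ln kappa) / ln 2
    E    = kappa * m * n * exp(-lambda * S)

where ``m`` is the query length and ``n`` the search-space length.  The
default parameters (BLOSUM62, 11/1, lambda = 0.267, kappa = 0.041) are the
long-standing gapped BLASTP defaults.

The dynamic programme is exact (no word seeding, no X-drop); the three-state
Gotoh recurrences are filled row-wise with integer arithmetic so tracebacks
are bit-reproducible.  Tie-breaking prefers the diagonal move, then a gap in
the subject, then a gap in the query.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

# residue order used to index the substitution matrix; X is neutral
RESIDUES = "ACDEFGHIKLMNPQRSTVWYX"
_INDEX = {aa: i for i, aa in enumerate(RESIDUES)}
_NEG = -(2**30)  # -infinity sentinel safe for int64 accumulation


def _load_matrix(name: str) -> np.ndarray:
    """Return a 21x21 integer matrix in RESIDUES order; X scores 0 vs all."""
    raw = substitution_matrices.load(name)
    mat = np.zeros((21, 21), dtype=np.int64)
    for i, a in enumerate(RESIDUES[:20]):
        for j, b in enumerate(RESIDUES[:20]):
            mat[i, j] = int(raw[a, b])
    # X (last row/col) stays 0: undetermined residues are scored neutrally
    return mat


@dataclass
class ScoringScheme:
    """Substitution matrix plus affine gap costs and Karlin-Altschul constants.

    lambda_ and kappa must correspond to the chosen matrix/gap combination;
    the defaults are the gapped BLOSUM62 11/1 values.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lambda_: float = 0.267
    kappa: float = 0.041
    matrix: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.matrix is None:
            self.matrix = _load_matrix(self.matrix_name)
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.shape != (21, 21):
            raise ValueError("substitution matrix must be 21x21 in RESIDUES order")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.lambda_ <= 0 or self.kappa <= 0:
            raise ValueError("lambda and kappa must be positive")

    def score(self, a: str, b: str) -> int:
        """Substitution score for a residue pair (X scores 0 against anything)."""
        return int(self.matrix[_INDEX[a], _INDEX[b]])

    def encode(self, seq: str) -> np.ndarray:
        return np.fromiter((_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))


def bit_score(raw_score: float, scheme: ScoringScheme) -> float:
    """Normalized (bit) score: (lambda*S - ln kappa) / ln 2."""
    return (scheme.lambda_ * raw_score - math.log(scheme.kappa)) / math.log(2.0)


def evalue(raw_score: float, m: int, n: int, scheme: ScoringScheme) -> float:
    """Expected number of chance alignments scoring >= S: kappa*m*n*exp(-lambda*S).

    ``m`` is the query length and ``n`` the total search-space length.
    """
    if m < 1 or n < 1:
        raise ValueError("query length and search-space length must be >= 1")
    return scheme.kappa * m * n * math.exp(-scheme.lambda_ * raw_score)


@dataclass(frozen=True)
class AlignmentResult:
    """A scored pairwise alignment.

    ``aligned_query``/``aligned_subject`` are equal-length gapped strings;
    ``aligned_columns`` counts residue-residue columns only (the BLAST
    "Identities" denominator), so ``percent_identity`` ignores gap columns.
    Spans are 1-based inclusive; an empty local alignment has spans (0, 0).
    """

    query_id: str
    subject_id: str
    aligned_query: str
    aligned_subject: str
    raw_score: int
    bit_score: float
    e_value: float
    n_identical: int
    aligned_columns: int
    percent_identity: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]

    def to_tabular(self) -> str:
        """One line in the BLAST outfmt-6-like convention."""
        return "\t".join(
            [
                self.query_id,
                self.subject_id,
                f"{self.percent_identity:.1f}",
                str(len(self.aligned_query)),
                f"{self.bit_score:.1f}",
                f"{self.e_value:.2g}",
            ]
        )


TABULAR_HEADER = "query\tsubject\tpct_identity\talignment_length\tbit_score\te_value"


def _fill(codes_a: np.ndarray, codes_b: np.ndarray, scheme: ScoringScheme, local: bool):
    """Fill the three Gotoh state matrices (M, Ix, Iy) with int64 scores.

    Ix holds alignments ending with a gap in the subject (query residue
    consumed, "up"); Iy with a gap in the query ("left").  Row-wise fill:
    M and Ix depend only on the previous row; Iy is recovered with a
    running-maximum trick over the current row, which is exact for integer
    affine gap costs.
    """
    m, n = len(codes_a), len(codes_b)
    go, ge = scheme.gap_open, scheme.gap_extend
    M = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    Ix = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    Iy = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    jidx = np.arange(n + 1, dtype=np.int64)
    if not local:
        M[0, 0] = 0
        Iy[0, 1:] = -go - ge * jidx[1:]
    for i in range(1, m + 1):
        svec = scheme.matrix[codes_a[i - 1]][codes_b]  # substitution scores vs row residue
        diag = np.maximum(np.maximum(M[i - 1, :-1], Ix[i - 1, :-1]), Iy[i - 1, :-1])
        if local:
            diag = np.maximum(diag, 0)
        M[i, 1:] = svec + diag
        Ix[i, :] = np.maximum(
            np.maximum(M[i - 1, :] - go - ge, Ix[i - 1, :] - ge), Iy[i - 1, :] - go - ge
        )
        if local:
            Ix[i, 0] = _NEG
        # Iy via prefix max: open from max(M, Ix) at column k, extend to j
        w = np.maximum(M[i, :], Ix[i, :]) + ge * jidx
        p = np.maximum.accumulate(w)
        Iy[i, 1:] = p[:-1] - go - ge * jidx[1:]
    return M, Ix, Iy


def _traceback(codes_a, codes_b, M, Ix, Iy, scheme, local, end_i, end_j, end_state):
    """Reconstruct one optimal path by exact integer comparisons.

    Source-state preference everywhere: M (diagonal) first, then Ix (gap in
    subject), then Iy (gap in query) -- fixed so output is reproducible.
    """
    go, ge = scheme.gap_open, scheme.gap_extend
    i, j, state = end_i, end_j, end_state
    moves: list[tuple[int, int]] = []  # (di, dj)
    while True:
        if local and state == "M":
            prev = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            if prev <= 0:
                moves.append((1, 1))
                i, j = i - 1, j - 1
                break
        if not local and (i == 0 and j == 0):
            break
        if state == "M":
            moves.append((1, 1))
            target = M[i, j] - scheme.matrix[codes_a[i - 1], codes_b[j - 1]]
            i, j = i - 1, j - 1
            if not local and i == 0 and j == 0:
                break
            if M[i, j] == target:
                state = "M"
            elif Ix[i, j] == target:
                state = "Ix"
            else:
                state = "Iy"
        elif state == "Ix":
            moves.append((1, 0))
            val = Ix[i, j]
            i = i - 1
            if M[i, j] - go - ge == val:
                state = "M"
            elif Ix[i, j] - ge == val:
                state = "Ix"
            else:
                state = "Iy"
            if not local and i == 0 and j == 0:
                break
        else:  # Iy
            moves.append((0, 1))
            val = Iy[i, j]
            j = j - 1
            if M[i, j] - go - ge == val:
                state = "M"
            elif Ix[i, j] - go - ge == val:
                state = "Ix"
            else:
                state = "Iy"
            if not local and i == 0 and j == 0:
                break
    moves.reverse()
    return i, j, moves


def _build_result(a_id, b_id, seq_a, seq_b, start_i, start_j, moves, raw, scheme, n_search):
    qa, sb = [], []
    i, j = start_i, start_j
    for di, dj in moves:
        qa.append(seq_a[i] if di else "-")
        sb.append(seq_b[j] if dj else "-")
        i += di
        j += dj
    aligned_q, aligned_s = "".join(qa), "".join(sb)
    pairs = [(x, y) for x, y in zip(aligned_q, aligned_s) if x != "-" and y != "-"]
    n_ident = sum(1 for x, y in pairs if x == y)
    ncols = len(pairs)
    pid = 100.0 * n_ident / ncols if ncols else 0.0
    qspan = (start_i + 1, i) if i > start_i else (0, 0)
    sspan = (start_j + 1, j) if j > start_j else (0, 0)
    return AlignmentResult(
        query_id=a_id,
        subject_id=b_id,
        aligned_query=aligned_q,
        aligned_subject=aligned_s,
        raw_score=int(raw),
        bit_score=bit_score(raw, scheme),
        e_value=evalue(raw, max(len(seq_a), 1), n_search, scheme),
        n_identical=n_ident,
        aligned_columns=ncols,
        percent_identity=pid,
        query_span=qspan,
        subject_span=sspan,
    )


def align_global(a, b, scheme: ScoringScheme | None = None, search_space: int | None = None) -> AlignmentResult:
    """Optimal global alignment (Needleman-Wunsch with affine gaps).

    ``a`` and ``b`` may be ProteinRecord-like objects (with ``record_id``
    and ``sequence``) or plain strings.  ``search_space`` sets the n used by
    the E-value (default: subject length).
    """
    a_id, seq_a = _as_pair(a)
    b_id, seq_b = _as_pair(b)
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")
    scheme = scheme or ScoringScheme()
    ca, cb = scheme.encode(seq_a), scheme.encode(seq_b)
    M, Ix, Iy = _fill(ca, cb, scheme, local=False)
    m, n = len(ca), len(cb)
    candidates = [("M", M[m, n]), ("Ix", Ix[m, n]), ("Iy", Iy[m, n])]
    state, raw = max(candidates, key=lambda t: t[1])
    for st, val in candidates:  # preference order on ties
        if val == raw:
            state = st
            break
    si, sj, moves = _traceback(ca, cb, M, Ix, Iy, scheme, False, m, n, state)
    return _build_result(a_id, b_id, seq_a, seq_b, si, sj, moves, raw, scheme, search_space or n)


def align_local(a, b, scheme: ScoringScheme | None = None, search_space: int | None = None) -> AlignmentResult:
    """Optimal local alignment (Smith-Waterman with affine gaps).

    The empty alignment (score 0) is returned when no positive-scoring
    residue pairing exists.
    """
    a_id, seq_a = _as_pair(a)
    b_id, seq_b = _as_pair(b)
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")
    scheme = scheme or ScoringScheme()
    ca, cb = scheme.encode(seq_a), scheme.encode(seq_b)
    M, Ix, Iy = _fill(ca, cb, scheme, local=True)
    raw = int(M.max()) if M.size else 0
    n = len(cb)
    if raw <= 0:
        return _build_result(a_id, b_id, seq_a, seq_b, 0, 0, [], 0, scheme, search_space or n)
    end_i, end_j = np.unravel_index(int(np.argmax(M)), M.shape)  # row-major first max
    si, sj, moves = _traceback(ca, cb, M, Ix, Iy, scheme, True, int(end_i), int(end_j), "M")
    return _build_result(a_id, b_id, seq_a, seq_b, si, sj, moves, raw, scheme, search_space or n)


def _as_pair(x) -> tuple[str, str]:
    if isinstance(x, str):
        return ("query", x)
    return (x.record_id, x.sequence)
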
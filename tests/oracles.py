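"""Independent brute-force oracles for pairwise alignment.

These enumerate every gapped alignment path explicitly (no dynamic
programming, no memoisation) and are therefore independent of the DP
implementation they check.  Affine cost: a gap run of length L costs
gap_open + L * gap_extend.
"""

from __future__ import annotations


def brute_force_global(a: str, b: str, scheme) -> int:
    """Best global alignment score by exhaustive path enumeration."""
    go, ge = scheme.gap_open, scheme.gap_extend
    best = [-(10**9)]

    def rec(i: int, j: int, prev: str | None, score: int) -> None:
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "D", score + scheme.score(a[i], b[j]))
        if i < len(a):
            rec(i + 1, j, "U", score - (ge if prev == "U" else go + ge))
        if j < len(b):
            rec(i, j + 1, "L", score - (ge if prev == "L" else go + ge))

    rec(0, 0, None, 0)
    return best[0]


def brute_force_local(a: str, b: str, scheme) -> int:
    """Best local alignment score: any start, any stop, empty allowed (0)."""
    go, ge = scheme.gap_open, scheme.gap_extend
    best = [0]

    def rec(i: int, j: int, prev: str | None, score: int) -> None:
        if score > best[0]:
            best[0] = score
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "D", score + scheme.score(a[i], b[j]))
        if i < len(a):
            rec(i + 1, j, "U", score - (ge if prev == "U" else go + ge))
        if j < len(b):
            rec(i, j + 1, "L", score - (ge if prev == "L" else go + ge))

    for i0 in range(len(a)):
        for j0 in range(len(b)):
            rec(i0, j0, None, 0)
    return best[0]
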
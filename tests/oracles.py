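"""Independent reference implementations used only to check the package.

These deliberately share no code with intronmark: a three-state Gotoh DP and
a full alignment-path enumerator for alignment scores, and a naive
all-positions Hamming scan for primer binding.
"""

from __future__ import annotations

import itertools

NEG = float("-inf")


def gotoh_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = 5.0,
    gap_extend: float = 2.0,
) -> float:
    """Global affine-gap score; a gap of length L costs gap_open+gap_extend*L.

    End gaps are penalized like internal ones. Three-state Gotoh recurrence.
    """
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a residue vs gap)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                s = match if a[i - 1] == b[j - 1] else mismatch
                M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            if i > 0:
                X[i][j] = max(
                    M[i - 1][j] - gap_open - gap_extend,
                    X[i - 1][j] - gap_extend,
                    Y[i - 1][j] - gap_open - gap_extend,
                )
            if j > 0:
                Y[i][j] = max(
                    M[i][j - 1] - gap_open - gap_extend,
                    X[i][j - 1] - gap_open - gap_extend,
                    Y[i][j - 1] - gap_extend,
                )
    return max(M[n][m], X[n][m], Y[n][m])


def enumerate_alignment_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = 5.0,
    gap_extend: float = 2.0,
) -> float:
    """Brute-force maximum over ALL alignments (exponential; tiny inputs only).

    Walks every monotone path of M/X/Y moves, charging gap_open whenever a
    gap column does not continue a gap of the same kind.
    """
    best = [NEG]

    def walk(i: int, j: int, score: float, last: str) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            walk(i + 1, j + 1, score + s, "M")
        if i < len(a):
            cost = gap_extend if last == "X" else gap_open + gap_extend
            walk(i + 1, j, score - cost, "X")
        if j < len(b):
            cost = gap_extend if last == "Y" else gap_open + gap_extend
            walk(i, j + 1, score - cost, "Y")

    walk(0, 0, 0.0, "M")
    return best[0]


_COMP = str.maketrans("ACGTN", "TGCAN")


def naive_binding_scan(
    primer: str, template: str, max_mismatch: int, require_3prime_exact: bool = True
) -> list[tuple[str, int, int]]:
    """All-positions Hamming scan on both strands: (strand, pos5, mismatches)."""
    m = len(primer)
    rc = primer.translate(_COMP)[::-1]
    out = []
    for start in range(len(template) - m + 1):
        window = template[start : start + m]
        mm = sum(x != y for x, y in zip(primer, window))
        if mm <= max_mismatch and (
            not require_3prime_exact or primer[-3:] == window[-3:]
        ):
            out.append(("+", start, mm))
        mm_rc = sum(x != y for x, y in zip(rc, window))
        if mm_rc <= max_mismatch and (
            not require_3prime_exact or rc[:3] == window[:3]
        ):
            out.append(("-", start + m - 1, mm_rc))
    return sorted(out, key=lambda s: (s[1], s[0]))
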
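"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (plain
dynamic programming, exhaustive enumeration) and shares no code with the
package implementation it checks.
"""

from __future__ import annotations

NEG = float("-inf")


def global_affine_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = 5.0,
    gap_extend: float = 2.0,
) -> float:
    """Gotoh global alignment score; a gap of length L costs open + extend*L."""
    n, m = len(a), len(b)
    first = gap_open + gap_extend  # cost of the first gapped base
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + gap_extend * i)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + gap_extend * j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(
                M[i - 1][j] - first, X[i - 1][j] - gap_extend, Y[i - 1][j] - first
            )
            Y[i][j] = max(
                M[i][j - 1] - first, Y[i][j - 1] - gap_extend, X[i][j - 1] - first
            )
    return max(M[n][m], X[n][m], Y[n][m])


def semiglobal_read_score(
    read: str,
    ref: str,
    mismatch: float = 6.0,
    gap_open: float = 1.0,
    gap_extend: float = 6.0,
) -> float:
    """Read end-to-end vs reference with free reference end gaps.

    Matches score 0, N is free against anything; a gap of length L costs
    gap_open + gap_extend * L on either side.
    """
    m, n = len(read), len(ref)
    first = gap_open + gap_extend

    def sub(x: str, y: str) -> float:
        if x == "N" or y == "N":
            return 0.0
        return 0.0 if x == y else -mismatch

    # rows: read position consumed; cols: reference position consumed
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    I = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in ref (consumes read)
    D = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in read (consumes ref)
    for j in range(n + 1):
        M[0][j] = 0.0  # free leading reference
    for i in range(1, m + 1):
        for j in range(n + 1):
            if j > 0:
                s = sub(read[i - 1], ref[j - 1])
                M[i][j] = s + max(M[i - 1][j - 1], I[i - 1][j - 1], D[i - 1][j - 1])
                D[i][j] = max(
                    M[i][j - 1] - first, D[i][j - 1] - gap_extend, I[i][j - 1] - first
                )
            I[i][j] = max(
                M[i - 1][j] - first, I[i - 1][j] - gap_extend, D[i - 1][j] - first
            )
    return max(max(M[m]), max(I[m]), max(D[m]))  # free trailing reference


def brute_force_markers(type_refs: dict[str, str], k: int) -> dict[str, set[str]]:
    """Per type, all k-mers absent (both orientations) from every other type."""
    comp = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}

    def rc(s: str) -> str:
        return "".join(comp[c] for c in reversed(s))

    def all_kmers(seq: str) -> set[str]:
        return {seq[i : i + k] for i in range(len(seq) - k + 1)}

    out: dict[str, set[str]] = {}
    for label, seq in type_refs.items():
        own = all_kmers(seq)
        others: set[str] = set()
        for other_label, other_seq in type_refs.items():
            if other_label != label:
                kmers = all_kmers(other_seq)
                others |= kmers | {rc(x) for x in kmers}
        out[label] = {x for x in own if x not in others and rc(x) not in others}
    return out


def brute_force_matches(
    target: str, utr: str, min_length: int
) -> set[tuple[int, int, int]]:
    """All maximal ungapped matches >= min_length as (utr_start, target_start, length).

    1-based start coordinates on UTR and on *target* (the already-oriented
    comparison string).
    """
    n, m = len(utr), len(target)
    out: set[tuple[int, int, int]] = set()
    for i in range(n):
        for j in range(m):
            if utr[i] != target[j]:
                continue
            if i > 0 and j > 0 and utr[i - 1] == target[j - 1]:
                continue  # not left-maximal
            length = 0
            while i + length < n and j + length < m and utr[i + length] == target[j + length]:
                length += 1
            if length >= min_length:
                out.add((i + 1, j + 1, length))
    return out
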
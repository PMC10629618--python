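"""Independent reference implementations used only to check the package.

These deliberately share no code with :mod:`cggtools`: the segment oracle
enumerates every contiguous segment; the local-alignment oracle is a
pure-Python affine-gap dynamic program written from the recurrences; and
for tiny strings an exponential enumeration over all monotone residue
matchings validates the DP oracle itself.
"""

from __future__ import annotations

from itertools import combinations


def max_segment_bruteforce(seq: str, target: str, matrix) -> tuple[int, int | None, int | None]:
    """Best-scoring contiguous segment of position scores vs ``target``.

    Enumerates every (i, j) segment. Returns (score, start, end) with a
    1-based inclusive span; (0, None, None) if no positive segment exists.
    Ties: leftmost start, then shortest.
    """
    n = len(seq)
    best = (0, None, None)
    for i in range(n):
        total = 0
        for j in range(i, n):
            total += int(matrix[seq[j], target])
            if total > best[0]:
                best = (total, i + 1, j + 1)
    return best


def sw_score_bruteforce(a: str, b: str, matrix, gap_open: int, gap_extend: int) -> int:
    """Optimal local alignment score, affine gaps (length-k gap costs
    open + k*extend), via an explicit three-state dynamic program."""
    go = gap_open + gap_extend  # cost of the first gapped position
    ge = gap_extend
    n, m = len(a), len(b)
    NEG = float("-inf")
    best = 0
    M = [[0] * (m + 1) for _ in range(n + 1)]  # ends in a match/mismatch
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # ends in a gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # ends in a gap in a
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = int(matrix[a[i - 1], b[j - 1]])
            M[i][j] = max(0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - go, X[i - 1][j] - ge)
            Y[i][j] = max(M[i][j - 1] - go, Y[i][j - 1] - ge)
            best = max(best, M[i][j])
    return best


def sw_score_enumeration(a: str, b: str, matrix, gap_open: int, gap_extend: int) -> int:
    """Local alignment score by exhaustive enumeration of every monotone
    matching of positions (feasible only for tiny strings).

    A local alignment is an ordered set of aligned pairs; unaligned
    stretches between consecutive pairs are internal gaps charged
    open + len*extend per sequence. Terminal unaligned residues are free.
    """
    n, m = len(a), len(b)
    best = 0
    positions_a = range(n)
    positions_b = range(m)
    for k in range(1, min(n, m) + 1):
        for ia in combinations(positions_a, k):
            for ib in combinations(positions_b, k):
                score = sum(int(matrix[a[i], b[j]]) for i, j in zip(ia, ib))
                for t in range(1, k):
                    da = ia[t] - ia[t - 1] - 1
                    db = ib[t] - ib[t - 1] - 1
                    if da:
                        score -= gap_open + da * gap_extend
                    if db:
                        score -= gap_open + db * gap_extend
                best = max(best, score)
    return best
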
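"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-derivations (plain dynamic programming,
pair enumeration) kept separate from the library code they check.
"""

from __future__ import annotations

NEG = float("-inf")


def sw_score(query: str, target: str, pair_score, gap_open: int, gap_extend: int) -> int:
    """Smith-Waterman local alignment score by explicit Gotoh recursion.

    A gap of length n costs gap_open + (n - 1) * gap_extend.
    """
    n, m = len(query), len(target)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]   # ends in a substitution
    X = [[NEG] * (m + 1) for _ in range(n + 1)]   # ends in a gap in target
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]   # ends in a gap in query
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = pair_score(query[i - 1], target[j - 1])
            M[i][j] = max(0.0,
                          M[i - 1][j - 1] + s,
                          X[i - 1][j - 1] + s,
                          Y[i - 1][j - 1] + s)
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend)
            best = max(best, M[i][j])
    return int(best)


def kendall_concordance(observed_ranks) -> float:
    """Kendall tau-a by explicit pair enumeration (no ties expected)."""
    n = len(observed_ranks)
    if n < 2:
        return 1.0
    concordant = discordant = 0
    for i in range(n):
        for j in range(i + 1, n):
            d = observed_ranks[j] - observed_ranks[i]
            if d > 0:
                concordant += 1
            elif d < 0:
                discordant += 1
    return (concordant - discordant) / (n * (n - 1) / 2)
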
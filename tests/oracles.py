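"""Independent brute-force oracles used by the tests.

These are deliberately naive, textbook implementations kept separate from
the package: an exhaustive three-state affine local-alignment DP (scores
only) and the closed-form expectation value. They share nothing with
``isosip._align`` beyond the scoring convention (a gap of length k costs
open + k * extend).
"""

import math

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
NEG = float("-inf")


def blosum62_score(x: str, y: str) -> int:
    return int(_BLOSUM62[x, y])


def oracle_local_score(a: str, b: str, sub=blosum62_score,
                       gap_open: int = 11, gap_extend: int = 1) -> int:
    """Exhaustive Smith-Waterman/Gotoh local score via full 3-state DP."""
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ia = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    Ib = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ia[i][j] = max(max(M[i][j - 1], Ib[i][j - 1])
                           - gap_open - gap_extend,
                           Ia[i][j - 1] - gap_extend)
            Ib[i][j] = max(max(M[i - 1][j], Ia[i - 1][j])
                           - gap_open - gap_extend,
                           Ib[i - 1][j] - gap_extend)
            s = sub(a[i - 1], b[j - 1])
            M[i][j] = s + max(0.0, M[i - 1][j - 1], Ia[i - 1][j - 1],
                              Ib[i - 1][j - 1])
            best = max(best, M[i][j], Ia[i][j], Ib[i][j])
    return int(best)


def oracle_evalue(score: float, m: int, n: int,
                  lam: float = 0.267, K: float = 0.041) -> float:
    return K * m * n * math.exp(-lam * score)
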
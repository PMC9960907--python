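"""Independent brute-force oracle for local alignment scores.

Uses a single H matrix with explicit enumeration of every possible gap length
at each cell (O(n*m*(n+m))), a deliberately different formulation from the
three-matrix affine recurrence in the package, so the two can cross-check
each other.
"""

import numpy as np
from Bio.Align import substitution_matrices

_MAT = substitution_matrices.load("BLOSUM62")
_IDX = {aa: i for i, aa in enumerate(_MAT.alphabet)}


def blosum62(a: str, b: str) -> int:
    return int(_MAT[_IDX.get(a, _IDX["X"]), _IDX.get(b, _IDX["X"])])


def sw_score_bruteforce(query: str, target: str,
                        gap_open: int = 11, gap_extend: int = 1) -> int:
    """Optimal Smith-Waterman score; gap of length L costs gap_open + L*gap_extend."""
    n, m = len(query), len(target)
    H = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = H[i - 1, j - 1] + blosum62(query[i - 1], target[j - 1])
            if j > 0:
                ks = np.arange(1, j + 1)
                best = max(best, (H[i, j - ks] - gap_open - ks * gap_extend).max())
            if i > 0:
                ks = np.arange(1, i + 1)
                best = max(best, (H[i - ks, j] - gap_open - ks * gap_extend).max())
            H[i, j] = max(0.0, best)
    return int(H.max())


AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_pair(rng: np.random.Generator, lo: int = 5, hi: int = 40) -> tuple[str, str]:
    nq = int(rng.integers(lo, hi + 1))
    nt = int(rng.integers(lo, hi + 1))
    q = "".join(rng.choice(list(AA20), size=nq))
    t = "".join(rng.choice(list(AA20), size=nt))
    return q, t
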
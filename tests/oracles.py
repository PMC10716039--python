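"""Independent brute-force oracles used by the alignment tests.

These enumerate alignments explicitly and stay independent of the DP code
paths they check.
"""

import itertools


def brute_force_free_end_gaps(a: str, b: str, match=1, mis=-1, gap=-1) -> int:
    """Best score over every monotone alignment; unaligned ends of either
    sequence are free, gaps between aligned columns are penalized."""
    best = 0  # the empty alignment (everything end-gapped) scores 0
    la, lb = len(a), len(b)
    for k in range(1, min(la, lb) + 1):
        for A in itertools.combinations(range(la), k):
            for B in itertools.combinations(range(lb), k):
                s = 0
                for (i, j) in zip(A, B):
                    s += match if a[i] == b[j] else mis
                for (i1, j1), (i2, j2) in zip(zip(A, B), zip(A[1:], B[1:])):
                    s += gap * ((i2 - i1 - 1) + (j2 - j1 - 1))
                best = max(best, s)
    return best
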
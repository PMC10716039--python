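"""Alignment kernels (numba-compiled).

Alignment mode is free-end-gap: unaligned prefixes and suffixes of either
sequence cost nothing, while gaps inside the aligned span are penalized.
Under the package's unit scoring this is realised by the zero-floored
(Smith-Waterman-style) recurrence with the score taken at the best cell; it
suits barcode reads that carry adapter or binding-region sequence beyond
the barcode, and it is symmetric in its two arguments.

Bases are encoded A=0, C=1, G=2, T=3, N=-1; N never matches anything.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_CODE = np.full(256, -2, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_CODE[ord("N")] = -1


def encode_seq(seq: str, name: str = "sequence") -> np.ndarray:
    """Encode an uppercase ACGTN string; errors name the offending position."""
    if not seq:
        raise ValueError(f"{name} must be nonempty")
    codes = _CODE[np.frombuffer(seq.encode("ascii", "replace"), dtype=np.uint8)]
    bad = np.flatnonzero(codes == -2)
    if bad.size:
        raise ValueError(
            f"{name} contains non-ACGTN symbol {seq[bad[0]]!r} at position {bad[0] + 1}"
        )
    return codes


@njit(cache=True)
def fill_matrix(read, bc, match, mismatch, gap):
    n, m = len(read), len(bc)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    for i in range(1, n + 1):
        ri = read[i - 1]
        for j in range(1, m + 1):
            s = match if (ri == bc[j - 1] and ri >= 0) else mismatch
            best = H[i - 1, j - 1] + s
            up = H[i - 1, j] + gap
            if up > best:
                best = up
            left = H[i, j - 1] + gap
            if left > best:
                best = left
            if best < 0:  # free start: drop any negative-scoring prefix
                best = 0
            H[i, j] = best
    return H


@njit(cache=True)
def best_end(H):
    """Best-scoring cell; ties resolved by row-major scan order (first wins)."""
    bi, bj = 0, 0
    best = H[0, 0]
    for i in range(H.shape[0]):
        for j in range(H.shape[1]):
            if H[i, j] > best:
                best, bi, bj = H[i, j], i, j
    return best, bi, bj


@njit(cache=True)
def traceback_counts(H, read, bc, match, mismatch, gap, end_i, end_j, first_y):
    """Walk the optimal path; count aligned bases and mismatch classes.

    Move preference on ties: diagonal, then up (read base vs gap), then left
    (barcode base vs gap). Substitutions and all internal gap columns count
    toward ``mismatches_total``; the first-``first_y``-bases window is
    measured in barcode coordinates and counts substitutions and read gaps
    (barcode base against gap).
    """
    i, j = end_i, end_j
    aligned = 0
    mm_total = 0
    mm_first = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        ri = read[i - 1]
        s = match if (ri == bc[j - 1] and ri >= 0) else mismatch
        if H[i, j] == H[i - 1, j - 1] + s:
            aligned += 1
            if s == mismatch:
                mm_total += 1
                if j <= first_y:
                    mm_first += 1
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + gap:
            mm_total += 1  # read base against gap
            i -= 1
        else:
            mm_total += 1  # barcode base against gap
            if j <= first_y:
                mm_first += 1
            j -= 1
    return aligned, mm_total, mm_first, i, j


@njit(cache=True)
def score_pair(read, bc, match, mismatch, gap):
    """Score-only free-end-gap DP with a two-row rolling matrix."""
    n, m = len(read), len(bc)
    prev = np.zeros(m + 1, dtype=np.int32)
    cur = np.zeros(m + 1, dtype=np.int32)
    best = np.int32(0)
    for i in range(1, n + 1):
        cur[0] = 0
        ri = read[i - 1]
        for j in range(1, m + 1):
            s = match if (ri == bc[j - 1] and ri >= 0) else mismatch
            b = prev[j - 1] + s
            u = prev[j] + gap
            if u > b:
                b = u
            l = cur[j - 1] + gap
            if l > b:
                b = l
            if b < 0:
                b = 0
            cur[j] = b
            if b > best:
                best = b
        prev, cur = cur, prev
    return best


@njit(cache=True)
def score_library(read, lib, match, mismatch, gap):
    """Scores of one read against every row of a 2-D encoded barcode array."""
    out = np.empty(lib.shape[0], dtype=np.int32)
    for k in range(lib.shape[0]):
        out[k] = score_pair(read, lib[k], match, mismatch, gap)
    return out
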
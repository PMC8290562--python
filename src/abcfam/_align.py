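"""Smith-Waterman kernels for position-specific scoring matrices.

The recursion uses three states with affine gaps and no direct
insertion<->deletion transitions:

    M[i,j]  = max(0, M[i-1,j-1], Ix[i-1,j-1], Iy[i-1,j-1]) + S[i-1,j-1]
    Ix[i,j] = max(M[i-1,j] + gap_open, Ix[i-1,j] + gap_extend)
    Iy[i,j] = max(M[i,j-1] + gap_open, Iy[i,j-1] + gap_extend)

where ``S`` holds the position-specific match scores (sequence rows x
profile columns, half-bit units) and the local alignment score is
``max(0, max M)``.  The numba kernels are score-identical to a naive
enumeration of all alignment start/end pairs under this state model.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e30


@njit(cache=True)
def sw_best_score(S, gap_open, gap_extend):
    """Best local alignment score (score-only, two rolling rows)."""
    n, m = S.shape
    prev_m = np.zeros(m + 1)
    prev_ix = np.full(m + 1, NEG)
    prev_iy = np.full(m + 1, NEG)
    cur_m = np.zeros(m + 1)
    cur_ix = np.full(m + 1, NEG)
    cur_iy = np.full(m + 1, NEG)
    best = 0.0
    for i in range(1, n + 1):
        cur_m[0] = 0.0
        cur_ix[0] = NEG
        cur_iy[0] = NEG
        for j in range(1, m + 1):
            prev = prev_m[j - 1]
            if prev_ix[j - 1] > prev:
                prev = prev_ix[j - 1]
            if prev_iy[j - 1] > prev:
                prev = prev_iy[j - 1]
            if prev < 0.0:
                prev = 0.0
            cur_m[j] = prev + S[i - 1, j - 1]
            a = prev_m[j] + gap_open
            b = prev_ix[j] + gap_extend
            cur_ix[j] = a if a > b else b
            a = cur_m[j - 1] + gap_open
            b = cur_iy[j - 1] + gap_extend
            cur_iy[j] = a if a > b else b
            if cur_m[j] > best:
                best = cur_m[j]
        prev_m, cur_m = cur_m, prev_m
        prev_ix, cur_ix = cur_ix, prev_ix
        prev_iy, cur_iy = cur_iy, prev_iy
    return best


@njit(cache=True)
def sw_matrices(S, gap_open, gap_extend):
    """Full M/Ix/Iy matrices, (n+1) x (m+1), for traceback."""
    n, m = S.shape
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            prev = M[i - 1, j - 1]
            if Ix[i - 1, j - 1] > prev:
                prev = Ix[i - 1, j - 1]
            if Iy[i - 1, j - 1] > prev:
                prev = Iy[i - 1, j - 1]
            if prev < 0.0:
                prev = 0.0
            M[i, j] = prev + S[i - 1, j - 1]
            a = M[i - 1, j] + gap_open
            b = Ix[i - 1, j] + gap_extend
            Ix[i, j] = a if a > b else b
            a = M[i, j - 1] + gap_open
            b = Iy[i, j - 1] + gap_extend
            Iy[i, j] = a if a > b else b
    return M, Ix, Iy


def traceback(M, Ix, Iy, S, gap_open, gap_extend, end_i, end_j):
    """Recover the local alignment path ending in a match at (end_i, end_j).

    Returns (seq_start, seq_end, prof_start, prof_end, matched_pairs) with
    0-based half-open coordinates; matched_pairs lists the (i, j) 0-based
    index pairs aligned in the match state, in ascending order.
    """
    tol = 1e-6
    i, j = end_i, end_j
    state = "M"
    pairs = []
    while True:
        if state == "M":
            pairs.append((i - 1, j - 1))
            dm = M[i - 1, j - 1]
            dix = Ix[i - 1, j - 1]
            diy = Iy[i - 1, j - 1]
            best_prev = max(dm, dix, diy)
            if best_prev <= tol:  # predecessor was the empty alignment
                break
            if abs(best_prev - dm) <= tol:
                state = "M"
            elif abs(best_prev - dix) <= tol:
                state = "Ix"
            else:
                state = "Iy"
            i -= 1
            j -= 1
        elif state == "Ix":
            if abs(Ix[i, j] - (M[i - 1, j] + gap_open)) <= tol:
                state = "M"
            else:
                state = "Ix"
            i -= 1
        else:  # Iy
            if abs(Iy[i, j] - (M[i, j - 1] + gap_open)) <= tol:
                state = "M"
            else:
                state = "Iy"
            j -= 1
    pairs.reverse()
    seq_start = pairs[0][0]
    prof_start = pairs[0][1]
    seq_end = pairs[-1][0] + 1
    prof_end = pairs[-1][1] + 1
    return seq_start, seq_end, prof_start, prof_end, pairs
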
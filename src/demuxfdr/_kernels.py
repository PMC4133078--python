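"""Numba-compiled dynamic-programming kernels.

All kernels operate on uint8-encoded sequences (A=0, C=1, G=2, T=3; the
value 4 is reserved as padding and never matches any base).
"""

import numpy as np
from numba import njit

PAD = np.uint8(4)


@njit(cache=True)
def sl_distance_kernel(a, b):
    """Sequence-Levenshtein distance between two encoded sequences.

    Minimum over the last row and last column of the Levenshtein DP
    matrix, i.e. the minimal number of edits turning one sequence into
    any prefix of the other (or vice versa).
    """
    la = a.shape[0]
    lb = b.shape[0]
    prev = np.empty(lb + 1, np.int32)
    cur = np.empty(lb + 1, np.int32)
    for j in range(lb + 1):
        prev[j] = j
    best = np.int32(lb)  # dp[0][lb]
    for i in range(1, la + 1):
        cur[0] = i
        ai = a[i - 1]
        for j in range(1, lb + 1):
            cost = 0 if ai == b[j - 1] else 1
            d = prev[j - 1] + cost
            if prev[j] + 1 < d:
                d = prev[j] + 1
            if cur[j - 1] + 1 < d:
                d = cur[j - 1] + 1
            cur[j] = d
        if cur[lb] < best:
            best = cur[lb]
        prev, cur = cur, prev
    # prev now holds the last row
    for j in range(lb + 1):
        if prev[j] < best:
            best = prev[j]
    return best


@njit(cache=True)
def batch_distance_kernel(queries, lengths, refs, ref_lengths):
    """Pairwise SL distances between padded query rows and reference rows.

    queries: (n, W) uint8, padded with PAD beyond each row's length.
    lengths: (n,) effective query lengths.
    refs: (k, L) uint8, padded; ref_lengths: (k,).
    Returns (n, k) int32 distance matrix.
    """
    n = queries.shape[0]
    k = refs.shape[0]
    out = np.empty((n, k), np.int32)
    maxl = refs.shape[1]
    prev = np.empty(maxl + 1, np.int32)
    cur = np.empty(maxl + 1, np.int32)
    for r in range(k):
        lb = ref_lengths[r]
        for q in range(n):
            la = lengths[q]
            for j in range(lb + 1):
                prev[j] = j
            best = np.int32(lb)
            for i in range(1, la + 1):
                cur[0] = i
                ai = queries[q, i - 1]
                for j in range(1, lb + 1):
                    cost = 0 if ai == refs[r, j - 1] else 1
                    d = prev[j - 1] + cost
                    if prev[j] + 1 < d:
                        d = prev[j] + 1
                    if cur[j - 1] + 1 < d:
                        d = cur[j - 1] + 1
                    cur[j] = d
                if cur[lb] < best:
                    best = cur[lb]
                for j in range(lb + 1):
                    t = prev[j]
                    prev[j] = cur[j]
                    cur[j] = t
            for j in range(lb + 1):
                if prev[j] < best:
                    best = prev[j]
            out[q, r] = best
    return out


@njit(cache=True)
def filter_compatible_kernel(candidates, ref, dmin):
    """Boolean mask of candidate rows with SL distance >= dmin to `ref`.

    candidates: (n, l) uint8 (all full length); ref: (l,) uint8.
    """
    n = candidates.shape[0]
    out = np.empty(n, np.bool_)
    for q in range(n):
        out[q] = sl_distance_kernel(candidates[q], ref) >= dmin
    return out
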
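"""Numba kernels for Jaro / Jaro-Winkler similarity.

The kernels operate on int32 symbol arrays (Unicode code points for
character-level comparison, token ids for token-level comparison) so the
same code path serves both string modes and the quadratic pairwise
context-window sums.  All public entry points live in
:mod:`ctxsel.context_similarity`; this module is implementation detail.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _jaro_core(s1, len1, s2, len2, flags1, flags2):
    # Standard Jaro similarity: matches inside a sliding window of
    # floor(max(|s1|,|s2|)/2) - 1, transpositions = half the number of
    # matched symbols that disagree in matching order.
    if len1 == 0 and len2 == 0:
        return 1.0
    if len1 == 0 or len2 == 0:
        return 0.0
    maxlen = len1 if len1 > len2 else len2
    window = maxlen // 2 - 1
    if window < 0:
        window = 0
    for i in range(len1):
        flags1[i] = False
    for j in range(len2):
        flags2[j] = False
    m = 0
    for i in range(len1):
        lo = i - window
        if lo < 0:
            lo = 0
        hi = i + window + 1
        if hi > len2:
            hi = len2
        for j in range(lo, hi):
            if (not flags2[j]) and s2[j] == s1[i]:
                flags1[i] = True
                flags2[j] = True
                m += 1
                break
    if m == 0:
        return 0.0
    t = 0
    k = 0
    for i in range(len1):
        if flags1[i]:
            while not flags2[k]:
                k += 1
            if s1[i] != s2[k]:
                t += 1
            k += 1
    half = t // 2
    return (m / len1 + m / len2 + (m - half) / m) / 3.0


@njit(cache=True)
def _jaro_winkler_core(s1, len1, s2, len2, flags1, flags2, p, lmax, bt):
    j = _jaro_core(s1, len1, s2, len2, flags1, flags2)
    if j >= bt:
        limit = len1 if len1 < len2 else len2
        if lmax < limit:
            limit = lmax
        ell = 0
        while ell < limit and s1[ell] == s2[ell]:
            ell += 1
        j = j + ell * p * (1.0 - j)
    return j


@njit(cache=True)
def _pairwise_context_sum(codes, lengths, weights, base, p, lmax, bt):
    """Sum of pair similarities over all unordered window pairs.

    ``codes``: (n_windows, n_widths, maxlen) int32 symbol array, one row of
    context strings per window (widths v = 1..W).  ``weights``: 1/(v+1) per
    width.  ``base`` is the constant v=0 contribution per pair (1.0 when the
    width-0 term is included, 0.0 otherwise).  Accumulation order matches the
    naive double loop exactly: pairs (i, j) with i < j, widths ascending,
    per-pair subtotal added to the running total.
    """
    n = codes.shape[0]
    n_widths = codes.shape[1]
    maxlen = codes.shape[2]
    flags1 = np.zeros(maxlen, dtype=np.bool_)
    flags2 = np.zeros(maxlen, dtype=np.bool_)
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            local = base
            for v in range(n_widths):
                sim = _jaro_winkler_core(
                    codes[i, v],
                    lengths[i, v],
                    codes[j, v],
                    lengths[j, v],
                    flags1,
                    flags2,
                    p,
                    lmax,
                    bt,
                )
                local += sim * weights[v]
            total += local
    return total


def encode_chars(s: str) -> np.ndarray:
    """Unicode code points of ``s`` as an int32 array."""
    if not s:
        return np.empty(0, dtype=np.int32)
    return np.frombuffer(s.encode("utf-32-le"), dtype=np.uint32).astype(np.int32)


def jaro_arrays(a1: np.ndarray, a2: np.ndarray) -> float:
    maxlen = max(len(a1), len(a2), 1)
    flags1 = np.zeros(maxlen, dtype=np.bool_)
    flags2 = np.zeros(maxlen, dtype=np.bool_)
    return _jaro_core(a1, len(a1), a2, len(a2), flags1, flags2)


def jaro_winkler_arrays(
    a1: np.ndarray, a2: np.ndarray, p: float, lmax: int, bt: float
) -> float:
    maxlen = max(len(a1), len(a2), 1)
    flags1 = np.zeros(maxlen, dtype=np.bool_)
    flags2 = np.zeros(maxlen, dtype=np.bool_)
    return _jaro_winkler_core(
        a1, len(a1), a2, len(a2), flags1, flags2, p, lmax, bt
    )
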
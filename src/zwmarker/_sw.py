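"""Affine-gap local alignment (Gotoh) kernel, numba-compiled.

Scoring convention: match +1, mismatch -2, a gap of length L costs
open + ext*L (default 5 + 2L), i.e. the first gap base pays open+ext and
every further base pays ext. The kernel returns the single best local
alignment with full traceback information.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MATCH = 1
MISMATCH = -2
GAP_OPEN = 5  # positive costs
GAP_EXT = 2

_NEG = -(10**9)

# pointer byte layout: bits 0-1 H-source (0 stop, 1 diag, 2 E, 3 F),
# bit 2: E extended from E, bit 3: F extended from F


@njit(cache=False)
def _fill(q, s, match, mismatch, gap_first, gap_ext):  # pragma: no cover - numba
    n = q.shape[0]
    m = s.shape[0]
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    h_prev = np.zeros(m + 1, dtype=np.int64)
    e_prev = np.full(m + 1, _NEG, dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        h_cur = np.zeros(m + 1, dtype=np.int64)
        e_cur = np.full(m + 1, _NEG, dtype=np.int64)
        f = _NEG
        for j in range(1, m + 1):
            e_open = h_prev[j] - gap_first
            e_extd = e_prev[j] - gap_ext
            if e_extd > e_open:
                e = e_extd
                ptr[i, j] |= 4
            else:
                e = e_open
            e_cur[j] = e
            f_open = h_cur[j - 1] - gap_first
            f_extd = f - gap_ext
            if f_extd > f_open:
                f = f_extd
                ptr[i, j] |= 8
            else:
                f = f_open
            sub = match if q[i - 1] == s[j - 1] else mismatch
            diag = h_prev[j - 1] + sub
            h = 0
            src = 0
            if diag > h:
                h = diag
                src = 1
            if e > h:
                h = e
                src = 2
            if f > h:
                h = f
                src = 3
            h_cur[j] = h
            ptr[i, j] |= src
            if h > best:
                best = h
                bi = i
                bj = j
        h_prev = h_cur
        e_prev = e_cur
    return best, bi, bj, ptr


@njit(cache=False)
def _traceback(q, s, bi, bj, ptr):  # pragma: no cover - numba
    i = bi
    j = bj
    matches = 0
    cols = 0
    state = 0  # 0 = H, 1 = E, 2 = F
    while i > 0 and j > 0:
        p = ptr[i, j]
        if state == 0:
            src = p & 3
            if src == 0:
                break
            if src == 1:
                cols += 1
                if q[i - 1] == s[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif src == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            cols += 1
            extended = (p & 4) != 0
            i -= 1
            if not extended:
                state = 0
            # re-read pointer at new cell next loop iteration
        else:
            cols += 1
            extended = (p & 8) != 0
            j -= 1
            if not extended:
                state = 0
    return i, j, matches, cols


def sw_align(query: str, subject: str,
             match: int = MATCH, mismatch: int = MISMATCH,
             gap_open: int = GAP_OPEN, gap_ext: int = GAP_EXT):
    """Best local alignment of ``query`` vs ``subject``.

    Returns ``(score, qstart, qend, sstart, send, matches, columns)`` with
    0-based inclusive coordinates, or ``None`` when the best score is 0.
    """
    q = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
    s = np.frombuffer(subject.encode("ascii"), dtype=np.uint8)
    if len(q) == 0 or len(s) == 0:
        return None
    best, bi, bj, ptr = _fill(q, s, match, mismatch, gap_open + gap_ext, gap_ext)
    if best <= 0:
        return None
    i0, j0, matches, cols = _traceback(q, s, bi, bj, ptr)
    return int(best), int(i0), int(bi - 1), int(j0), int(bj - 1), int(matches), int(cols)
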
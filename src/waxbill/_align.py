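"""Affine-gap dynamic-programming kernels (numba-compiled).

Two flavours are provided:

* semiglobal: the query (a transcript fragment or read) is aligned end to
  end against any window of the reference; reference overhangs are free.
* local: Smith-Waterman, used to extend seed hits during ortholog search.

Gap cost model: a gap of length L costs gap_open + L * gap_extend.
Tie-breaking is deterministic: diagonal > gap-in-query (reference base
unmatched) > gap-in-reference, and the smallest end column wins.
Sequences are encoded as uint8 (A,C,G,T -> 0..3; anything else 4, which
always scores as a mismatch).
"""
from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e30

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[ord(chr(_b).lower())] = _i


def encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


@njit(cache=True)
def _semiglobal_fill(q, r, match, mismatch, gap_open, gap_ext):
    m, n = q.shape[0], r.shape[0]
    h_prev = np.zeros(n + 1, dtype=np.float64)
    e_prev = np.full(n + 1, NEG, dtype=np.float64)
    ptr = np.zeros((m + 1, n + 1), dtype=np.uint8)
    for i in range(1, m + 1):
        h_cur = np.empty(n + 1, dtype=np.float64)
        e_cur = np.empty(n + 1, dtype=np.float64)
        # j = 0: query prefix aligned before reference start -> gap in ref
        e_open = h_prev[0] - gap_open - gap_ext
        e_extend = e_prev[0] - gap_ext
        if e_extend > e_open:
            e_cur[0] = e_extend
            ptr[i, 0] = 2 | 4
        else:
            e_cur[0] = e_open
            ptr[i, 0] = 2
        h_cur[0] = e_cur[0]
        f = NEG
        for j in range(1, n + 1):
            # E: gap in reference (vertical, consumes query base)
            e_open = h_prev[j] - gap_open - gap_ext
            e_extend = e_prev[j] - gap_ext
            eext = 0
            if e_extend > e_open:
                e = e_extend
                eext = 4
            else:
                e = e_open
            # F: gap in query (horizontal, consumes reference base)
            f_open = h_cur[j - 1] - gap_open - gap_ext
            f_extend = f - gap_ext
            fext = 0
            if f_extend > f_open:
                f = f_extend
                fext = 8
            else:
                f = f_open
            qa = q[i - 1]
            ra = r[j - 1]
            s = match if (qa == ra and qa < 4) else mismatch
            diag = h_prev[j - 1] + s
            if diag >= f and diag >= e:
                h_cur[j] = diag
                ptr[i, j] = 0 | eext | fext
            elif f >= e:
                h_cur[j] = f
                ptr[i, j] = 1 | eext | fext
            else:
                h_cur[j] = e
                ptr[i, j] = 2 | eext | fext
            e_cur[j] = e
        h_prev = h_cur
        e_prev = e_cur
    best_j = 0
    best = h_prev[0]
    for j in range(1, n + 1):
        if h_prev[j] > best:
            best = h_prev[j]
            best_j = j
    return best, best_j, ptr


@njit(cache=True)
def _local_fill(q, r, match, mismatch, gap_open, gap_ext):
    m, n = q.shape[0], r.shape[0]
    h_prev = np.zeros(n + 1, dtype=np.float64)
    e_prev = np.full(n + 1, NEG, dtype=np.float64)
    ptr = np.zeros((m + 1, n + 1), dtype=np.uint8)
    for j in range(n + 1):
        ptr[0, j] = 3
    for i in range(m + 1):
        ptr[i, 0] = 3
    best = 0.0
    best_i = 0
    best_j = 0
    for i in range(1, m + 1):
        h_cur = np.zeros(n + 1, dtype=np.float64)
        e_cur = np.empty(n + 1, dtype=np.float64)
        e_cur[0] = NEG
        f = NEG
        for j in range(1, n + 1):
            e_open = h_prev[j] - gap_open - gap_ext
            e_extend = e_prev[j] - gap_ext
            eext = 0
            if e_extend > e_open:
                e = e_extend
                eext = 4
            else:
                e = e_open
            f_open = h_cur[j - 1] - gap_open - gap_ext
            f_extend = f - gap_ext
            fext = 0
            if f_extend > f_open:
                f = f_extend
                fext = 8
            else:
                f = f_open
            qa = q[i - 1]
            ra = r[j - 1]
            s = match if (qa == ra and qa < 4) else mismatch
            diag = h_prev[j - 1] + s
            if diag >= f and diag >= e:
                h = diag
                choice = 0
            elif f >= e:
                h = f
                choice = 1
            else:
                h = e
                choice = 2
            if h <= 0.0:
                h = 0.0
                choice = 3
            h_cur[j] = h
            ptr[i, j] = choice | eext | fext
            e_cur[j] = e
            if h > best:
                best = h
                best_i = i
                best_j = j
        h_prev = h_cur
        e_prev = e_cur
    return best, best_i, best_j, ptr


def _traceback(ptr, i, j, stop_at_zero):
    """Walk pointers back to row 0 (semiglobal) or a zero cell (local).
    Returns columns [(query_pos | -1, ref_pos | -1)] in alignment order."""
    cols = []
    state = 0  # H
    while i > 0:
        p = ptr[i, j]
        if state == 0:
            choice = p & 3
            if stop_at_zero and choice == 3:
                break
            if choice == 0:
                cols.append((i - 1, j - 1))
                i -= 1
                j -= 1
            elif choice == 1:
                state = 1
            else:
                state = 2
        elif state == 1:  # F: gap in query
            cols.append((-1, j - 1))
            state = 1 if (p & 8) else 0
            j -= 1
        else:  # E: gap in reference
            cols.append((i - 1, -1))
            state = 2 if (p & 4) else 0
            i -= 1
    cols.reverse()
    return cols


def semiglobal_align(query: str, ref: str, match=2.0, mismatch=-3.0,
                     gap_open=5.0, gap_ext=2.0):
    """Optimal semiglobal affine alignment (free end gaps on the reference
    side only). Returns (score, columns)."""
    if not query or not ref:
        raise ValueError("empty sequence")
    score, best_j, ptr = _semiglobal_fill(
        encode(query), encode(ref), float(match), float(mismatch),
        float(gap_open), float(gap_ext))
    return score, _traceback(ptr, len(query), best_j, stop_at_zero=False)


def local_align(query: str, ref: str, match=1.0, mismatch=-2.0,
                gap_open=5.0, gap_ext=2.0):
    """Smith-Waterman local affine alignment. Returns (score, columns);
    columns may be empty when nothing scores above zero."""
    if not query or not ref:
        raise ValueError("empty sequence")
    score, bi, bj, ptr = _local_fill(
        encode(query), encode(ref), float(match), float(mismatch),
        float(gap_open), float(gap_ext))
    if score <= 0:
        return 0.0, []
    return score, _traceback(ptr, bi, bj, stop_at_zero=True)
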
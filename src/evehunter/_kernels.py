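"""Numeric extension kernels for the seed-and-extend search engine.

Both kernels operate on small-integer code arrays and an integer
substitution matrix whose last row/column is a sentinel scored -10000,
which makes extensions terminate at unit boundaries automatically.
They are JIT-compiled with numba when available; the pure-Python path is
identical and used as a fallback.
"""

from __future__ import annotations

import numpy as np

NEG = -(10**9)


def _ungapped_extend_right(q, s, qi, si, matrix, xdrop):
    """X-drop ungapped extension of q[qi:] vs s[si:]; returns (length, score)."""
    best = 0
    best_len = 0
    score = 0
    n = min(len(q) - qi, len(s) - si)
    for i in range(n):
        score += matrix[q[qi + i], s[si + i]]
        if score > best:
            best = score
            best_len = i + 1
        elif best - score > xdrop:
            break
    return best_len, best


def _banded_extend_right(q, s, qi, si, matrix, gap_open, gap_extend, xdrop, band):
    """Adaptive-band affine-gap X-drop extension of q[qi:] vs s[si:].

    Returns (dq, ds, score): the best-scoring alignment of q[qi:qi+dq]
    against s[si:si+ds], anchored at (qi, si). The band (width ``band``)
    is re-centred each row on the best cell of the previous row, so the
    alignment may drift arbitrarily far off the seed diagonal.
    """
    nq = len(q) - qi
    ns = len(s) - si
    if nq <= 0 or ns <= 0:
        return 0, 0, 0
    half = band // 2
    go = gap_open + gap_extend  # cost of the first gapped residue

    # Row 0: only horizontal moves (gaps in query / consuming s).
    lo = 0
    hi = min(ns + 1, band)
    m_prev = np.full(band, NEG, dtype=np.int64)
    y_prev = np.full(band, NEG, dtype=np.int64)
    x_prev = np.full(band, NEG, dtype=np.int64)
    m_prev[0] = 0
    for j in range(1, hi):
        y_prev[j] = go + gap_extend * (j - 1)
    best = 0
    best_i = 0
    best_j = 0
    prev_lo = lo

    m_cur = np.full(band, NEG, dtype=np.int64)
    y_cur = np.full(band, NEG, dtype=np.int64)
    x_cur = np.full(band, NEG, dtype=np.int64)

    center = 1
    for i in range(1, nq + 1):
        lo = center - half
        if lo < 0:
            lo = 0
        hi = lo + band
        if hi > ns + 1:
            hi = ns + 1
            lo = hi - band
            if lo < 0:
                lo = 0
        if lo >= hi:
            break
        for t in range(band):
            m_cur[t] = NEG
            y_cur[t] = NEG
            x_cur[t] = NEG
        row_best = NEG
        row_arg = lo
        qc = q[qi + i - 1]
        for j in range(lo, hi):
            t = j - lo
            pt = j - prev_lo
            # vertical: consume q_i, gap in s
            up_m = m_prev[pt] if 0 <= pt < band else NEG
            up_x = x_prev[pt] if 0 <= pt < band else NEG
            x_val = max(up_m + go, up_x + gap_extend)
            x_cur[t] = x_val
            # diagonal
            if j > 0:
                pd = j - 1 - prev_lo
                dm = m_prev[pd] if 0 <= pd < band else NEG
                dx = x_prev[pd] if 0 <= pd < band else NEG
                dy = y_prev[pd] if 0 <= pd < band else NEG
                d = dm
                if dx > d:
                    d = dx
                if dy > d:
                    d = dy
                if d > NEG // 2:
                    m_cur[t] = d + matrix[qc, s[si + j - 1]]
            # horizontal: gap in q, consume s_j
            if t > 0:
                y_val = max(m_cur[t - 1] + go, y_cur[t - 1] + gap_extend)
                y_cur[t] = y_val
            cell = m_cur[t]
            if x_cur[t] > cell:
                cell = x_cur[t]
            if y_cur[t] > cell:
                cell = y_cur[t]
            if cell > row_best:
                row_best = cell
                row_arg = j
            if m_cur[t] > best:
                best = m_cur[t]
                best_i = i
                best_j = j
        if row_best < best - xdrop:
            break
        center = row_arg + 1
        m_prev, m_cur = m_cur, m_prev
        x_prev, x_cur = x_cur, x_prev
        y_prev, y_cur = y_cur, y_prev
        prev_lo = lo
    return best_i, best_j, best


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    ungapped_extend_right = njit(cache=True)(_ungapped_extend_right)
    banded_extend_right = njit(cache=True)(_banded_extend_right)
except Exception:  # pragma: no cover
    ungapped_extend_right = _ungapped_extend_right
    banded_extend_right = _banded_extend_right
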
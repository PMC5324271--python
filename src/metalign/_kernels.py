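"""Numba-jitted alignment kernels.

Banded local (Smith-Waterman) alignment with linear gap costs.  The band is
centred on the expected diagonal of the anchored read and its half-width is
set from the normalized cutting distance by the caller.  Cells outside the
band are treated as score 0, i.e. a local alignment may restart at the band
edge; with an adequately wide band this never changes the optimum.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# traceback codes
_STOP, _DIAG, _UP, _LEFT = 0, 1, 2, 3


@njit(nogil=True)
def banded_sw(q, r, half_width, diag, match, mismatch, gap):
    """Banded Smith-Waterman of query ``q`` against reference window ``r``.

    ``diag`` is the expected column of query base 0 (band centre offset);
    the band at query row i covers columns [i+diag-hw, i+diag+hw].  Base
    code 4 (N) mismatches everything, including itself.

    Returns (score, q_start, r_start, q_end, r_end, steps) with 0-based
    half-open spans and ``steps`` an array of traceback codes
    (1=diag, 2=query-consuming gap, 3=reference-consuming gap) in
    alignment order.
    """
    m = q.size
    n = r.size
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    TB = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        lo = i + diag - half_width
        if lo < 1:
            lo = 1
        hi = i + diag + half_width
        if hi > n:
            hi = n
        qc = q[i - 1]
        for j in range(lo, hi + 1):
            rc = r[j - 1]
            if qc == rc and qc < 4:
                s = match
            else:
                s = mismatch
            v = H[i - 1, j - 1] + s
            t = _DIAG
            u = H[i - 1, j] + gap
            if u > v:
                v = u
                t = _UP
            w = H[i, j - 1] + gap
            if w > v:
                v = w
                t = _LEFT
            if v <= 0:
                v = 0
                t = _STOP
            H[i, j] = v
            TB[i, j] = t
            if v > best:
                best = v
                bi = i
                bj = j
    # traceback
    steps = np.empty(m + n, dtype=np.uint8)
    k = 0
    i = bi
    j = bj
    while i > 0 and j > 0 and TB[i, j] != _STOP:
        t = TB[i, j]
        steps[k] = t
        k += 1
        if t == _DIAG:
            i -= 1
            j -= 1
        elif t == _UP:
            i -= 1
        else:
            j -= 1
    return best, i, j, bi, bj, steps[:k][::-1].copy()


def steps_to_cigar(steps: np.ndarray, q_start: int, q_end: int, q_len: int) -> str:
    """Compress traceback steps to a CIGAR string with terminal soft clips."""
    ops = []
    if q_start > 0:
        ops.append((q_start, "S"))
    prev = None
    count = 0
    code_op = {1: "M", 2: "I", 3: "D"}
    for t in steps:
        op = code_op[int(t)]
        if op == prev:
            count += 1
        else:
            if prev is not None:
                ops.append((count, prev))
            prev = op
            count = 1
    if prev is not None:
        ops.append((count, prev))
    if q_len - q_end > 0:
        ops.append((q_len - q_end, "S"))
    return "".join(f"{c}{o}" for c, o in ops)
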
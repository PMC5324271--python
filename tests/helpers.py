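"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the package's index/DP code paths: hits come
from literal all-offset scans and alignment scores from a plain
full-matrix Smith-Waterman recurrence.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def rc(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int(((a != b) | (a == 4) | (b == 4)).sum())


def brute_force_hits(
    genome_codes: np.ndarray, q: np.ndarray, d: int
) -> List[Tuple[int, str, int]]:
    """All-offset, both-strand Hamming scan; (pos, strand, mismatches)."""
    n = genome_codes.size
    l = q.size
    out = []
    qr = rc(q)
    for o in range(n - l + 1):
        w = genome_codes[o : o + l]
        mm = hamming(w, q)
        if mm <= d:
            out.append((o, "+", mm))
        mm = hamming(w, qr)
        if mm <= d:
            out.append((o, "-", mm))
    out.sort(key=lambda h: (h[0], h[1]))
    return out


def brute_random_labels(genome_codes: np.ndarray, l: int, d: int) -> np.ndarray:
    """Per-offset random/repeat labels by an all-pairs Hamming scan.

    Offset o is random iff no window j != o (either strand) is within
    Hamming distance d of the window at o.  Labels cover offsets
    0 .. len-l-1 (the L - l convention).
    """
    from numpy.lib.stride_tricks import sliding_window_view

    W = sliding_window_view(genome_codes, l)
    n_win = W.shape[0]
    n_off = genome_codes.size - l
    labels = np.ones(n_off, dtype=bool)
    for o in range(n_off):
        w = W[o]
        mm_f = ((W != w) | (W == 4) | (w == 4)).sum(axis=1)
        wr = rc(w)
        mm_r = ((W != wr) | (W == 4) | (wr == 4)).sum(axis=1)
        others = np.ones(n_win, dtype=bool)
        others[o] = False
        if ((mm_f <= d) & others).any() or ((mm_r <= d) & others).any():
            labels[o] = False
    return labels


def brute_copy_counts(genome_codes: np.ndarray, l: int, d: int) -> np.ndarray:
    """Total hit count (both strands, self included) per l-mer offset."""
    from numpy.lib.stride_tricks import sliding_window_view

    W = sliding_window_view(genome_codes, l)
    n_off = genome_codes.size - l
    counts = np.zeros(n_off, dtype=np.int64)
    for o in range(n_off):
        w = W[o]
        mm_f = ((W != w) | (W == 4) | (w == 4)).sum(axis=1)
        wr = rc(w)
        mm_r = ((W != wr) | (W == 4) | (wr == 4)).sum(axis=1)
        counts[o] = int((mm_f <= d).sum() + (mm_r <= d).sum())
    return counts


def full_sw_score(
    q: np.ndarray, r: np.ndarray, match: int, mismatch: int, gap: int
) -> int:
    """Unbanded local-alignment score, linear gaps (vectorized rows)."""
    n = r.size
    idx = np.arange(n + 1, dtype=np.int64)
    prev = np.zeros(n + 1, dtype=np.int64)
    best = 0
    rr = r.astype(np.int64)
    for i in range(1, q.size + 1):
        qc = int(q[i - 1])
        s = np.where((rr == qc) & (rr < 4) & (qc < 4), match, mismatch)
        cur = np.zeros(n + 1, dtype=np.int64)
        cur[1:] = np.maximum(prev[:-1] + s, prev[1:] + gap)
        np.maximum(cur, 0, out=cur)
        # resolve the in-row left-gap chain in closed form
        cur = gap * idx + np.maximum.accumulate(cur - gap * idx)
        np.maximum(cur, 0, out=cur)
        best = max(best, int(cur.max()))
        prev = cur
    return best
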
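"""Mosaic repeat/random interval model and l-mer spectrum statistics.

A genome is viewed as a mosaic of *random* and *repeat* intervals: the
l-mer starting at an offset is random when no other genome location (on
either strand) lies within Hamming distance d of it, and repeat otherwise.
Because every read inherits the mosaic structure of its origin, the number
of random l-mers inside a read predicts how easily it can be anchored
uniquely; the histograms here summarise that distribution over all
read-length windows of a genome.

Offset convention: a window of length L carries L - l counted l-mer start
offsets (0 .. L-l-1) at step 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .core_index import (
    AnchorIndex,
    Genome,
    LOW_REPEAT,
    OVER_CAP,
    UNIQUE,
)

OVERLAPPING = "overlapping"
DISJOINT = "disjoint"


@dataclass
class IntervalLabeling:
    """Per-start-offset random/repeat labels of a genome at (l, d).

    ``random[o]`` is True when the l-mer at offset ``o`` has no other
    location within Hamming distance d.  ``has_n[o]`` marks l-mers that
    contain an N base.
    """

    l: int
    d: int
    random: np.ndarray
    has_n: np.ndarray


@dataclass
class SpectrumHistogram:
    """Three-bin histogram of qualifying l-mers per read-length window.

    Percentages of counted windows with zero qualifying l-mers, with a
    count in [1, mid_edge], and with more than mid_edge.  ``qualifier`` is
    ``random`` or ``low_repeat``; ``mode`` is overlapping or disjoint.
    """

    bin_zero: float
    bin_mid: float
    bin_high: float
    mode: str
    qualifier: str
    mid_edge: int
    n_windows: int


def extract_spectrum(window, l: int, step: int = 1) -> np.ndarray:
    """Start offsets of the l-mer spectrum of a read or window.

    Offsets are 0, step, 2*step, ... strictly less than L - l, so a read of
    length 1000 yields 960 overlapping 40-mers at step 1 and 24 disjoint
    ones at step 40.
    """
    if isinstance(window, (int, np.integer)):
        L = int(window)
    elif isinstance(window, str):
        L = len(window)
    else:
        L = window.length
    if step < 1:
        raise ValueError("step must be >= 1")
    if L <= l:
        raise ValueError("window too short")
    return np.arange(0, L - l, step)


def classify_intervals(
    genome: Genome,
    l: int,
    d: int,
    index: Optional[AnchorIndex] = None,
) -> IntervalLabeling:
    """Label every counted l-mer offset of ``genome`` as random or repeat.

    An offset is repeat iff the index finds at least one hit away from the
    offset itself; a hit at the offset's own position (forward self-match,
    or a reverse-strand self-match at a near-palindromic l-mer) never makes
    it a repeat.
    """
    if genome.length <= l:
        raise ValueError("genome too short for fragment length")
    idx = index if index is not None else AnchorIndex(genome, l, max(d, 0))
    codes = genome.codes
    n_off = genome.length - l
    random = np.ones(n_off, dtype=bool)
    has_n = _window_has_n(codes, l)[:n_off]
    # cap of 4 suffices: over_cap (>4 hits) implies >=3 non-self locations
    cap = 4
    for o in range(n_off):
        hl = idx.query(codes[o : o + l], d=d, cap=cap)
        if hl.status == OVER_CAP:
            random[o] = False
        else:
            random[o] = not any(h.ref_pos != o for h in hl.hits)
    return IntervalLabeling(l=l, d=d, random=random, has_n=has_n)


def random_fraction(labeling: IntervalLabeling) -> float:
    """Fraction of counted offsets labeled random."""
    if labeling.random.size == 0:
        raise ValueError("empty labeling")
    return float(labeling.random.mean())


def _window_has_n(codes: np.ndarray, w: int) -> np.ndarray:
    """Boolean per start offset: does the length-w window contain an N?"""
    isn = (codes == 4).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(isn)))
    return (cs[w:] - cs[:-w]) > 0


def _window_counts(flags: np.ndarray, L: int, l: int, mode: str) -> np.ndarray:
    """Per genome window of length L: number of flagged l-mer offsets.

    ``flags`` has one entry per l-mer start offset; window w counts offsets
    w .. w+L-l-1 (overlapping) or w, w+l, ... < w+L-l (disjoint).
    """
    span = L - l  # offsets counted per window
    n_win = flags.size - span + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.int64)
    if mode == OVERLAPPING:
        cs = np.concatenate(([0], np.cumsum(flags.astype(np.int64))))
        return cs[span:] - cs[: flags.size - span + 1]
    if mode == DISJOINT:
        k = (span + l - 1) // l  # number of disjoint offsets per window
        out = np.zeros(n_win, dtype=np.int64)
        for j in range(k):
            off = j * l
            if off >= span:
                break
            out += flags[off : off + n_win].astype(np.int64)
        return out
    raise ValueError(f"unknown mode {mode!r}")


def _binned(counts: np.ndarray, mid_edge: int, mode: str, qualifier: str) -> SpectrumHistogram:
    n = counts.size
    if n == 0:
        raise ValueError("no windows to count")
    zero = int((counts == 0).sum())
    mid = int(((counts >= 1) & (counts <= mid_edge)).sum())
    high = n - zero - mid
    return SpectrumHistogram(
        bin_zero=100.0 * zero / n,
        bin_mid=100.0 * mid / n,
        bin_high=100.0 * high / n,
        mode=mode,
        qualifier=qualifier,
        mid_edge=mid_edge,
        n_windows=n,
    )


def read_random_lmer_histogram(
    genome: Genome,
    L: int,
    l: int,
    d: int,
    mode: str = OVERLAPPING,
    mid_edge: int = 80,
    stride: int = 1,
    labeling: Optional[IntervalLabeling] = None,
) -> SpectrumHistogram:
    """Histogram of random l-mers over every length-L window of the genome.

    Windows containing an N base are excluded from the denominator.
    ``stride`` > 1 subsamples window starts for speed.
    """
    if L <= l:
        raise ValueError("window too short")
    if genome.length < L:
        raise ValueError("genome shorter than window length")
    lab = labeling if labeling is not None else classify_intervals(genome, l, d)
    counts = _window_counts(lab.random, L, l, mode)
    keep = ~_window_has_n(genome.codes, L)[: counts.size]
    counts = counts[keep][::stride]
    return _binned(counts, mid_edge, mode, "random")


def lmer_copy_classes(
    genome: Genome,
    l: int,
    d: int,
    cap: int,
    index: Optional[AnchorIndex] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-offset status flags (unique, low_repeat, over_cap) at list cap."""
    if genome.length <= l:
        raise ValueError("genome too short for fragment length")
    idx = index if index is not None else AnchorIndex(genome, l, max(d, 0))
    codes = genome.codes
    n_off = genome.length - l
    uniq = np.zeros(n_off, dtype=bool)
    low = np.zeros(n_off, dtype=bool)
    over = np.zeros(n_off, dtype=bool)
    for o in range(n_off):
        hl = idx.query(codes[o : o + l], d=d, cap=cap)
        if hl.status == UNIQUE:
            uniq[o] = True
        elif hl.status == LOW_REPEAT:
            low[o] = True
        elif hl.status == OVER_CAP:
            over[o] = True
    return uniq, low, over


def low_repeat_histogram(
    genome: Genome,
    L: int,
    l: int,
    d: int,
    cap: int,
    mode: str = OVERLAPPING,
    mid_edge: int = 80,
    stride: int = 1,
) -> SpectrumHistogram:
    """Histogram of low-repeat l-mers over the windows left after anchoring.

    Restricted to windows whose every l-mer is non-random (the reads the
    anchoring stage cannot handle); counts l-mers whose position list has
    between 2 and ``cap`` entries.
    """
    if cap < 2:
        raise ValueError("cap must be >= 2")
    if L <= l:
        raise ValueError("window too short")
    if genome.length < L:
        raise ValueError("genome shorter than window length")
    idx = AnchorIndex(genome, l, max(d, 0))
    uniq, low, _ = lmer_copy_classes(genome, l, d, cap, index=idx)
    # a window survives anchoring only if it has zero random l-mers
    n_random = _window_counts(uniq, L, l, OVERLAPPING)
    counts = _window_counts(low, L, l, mode)
    keep = (n_random == 0) & ~_window_has_n(genome.codes, L)[: counts.size]
    counts = counts[keep][::stride]
    return _binned(counts, mid_edge, mode, "low_repeat")
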
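"""The PE (parameter estimation) algorithm.

From a sample of N_t reads and the reference genome, estimate the
mismatch and indel error rates (eps_m_hat, eps_g_hat), choose the
fragment length / Hamming budget pair (l, d), and set the normalized
cutting distance for local alignment.

Rate estimation anchors the sample with (l, d) = (25, 2), locally aligns
every anchored read with a wide band, and counts mismatch and gap columns
per consumed reference base (soft-clipped ends are excluded, since
terminal error clusters would otherwise bias the rates upward).  Because
an insertion immediately followed by a deletion is string-identical to a
substitution, parsimonious alignment systematically under-counts indels;
the estimator removes this bias by parametric bootstrap: it simulates
reads from the reference at the raw observed rates, measures the bias of
its own counting procedure on them, and subtracts it.

The (l, d) selection evaluates d(l) = floor(eps_m_hat * l + 0.5) for each
candidate l in {15, 20, ..., 50}, anchors the sample with each pair, and
picks the cheapest l (by candidate positions enumerated in the index, a
hardware-independent cost proxy) among those anchoring within one
percentage point of the best rate.  Two parameter sets are emitted: a
speed-priority set (l, d, no sliding) and a mapping-priority set
(l, d + 1, S1 = l / 5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core_index import (
    AlignParams,
    AnchorIndex,
    FORWARD,
    Genome,
    Read,
    revcomp_codes,
)
from .alignment_stage import ANCHORED, anchor_reads, local_align
from .io import AlignmentRecord, _CIGAR_RE
from .read_sim import ErrorModel, simulate_reads

CANDIDATE_LS: Tuple[int, ...] = (15, 20, 25, 30, 35, 40, 45, 50)
PE_L = 25
PE_D = 2


@dataclass
class ErrorEstimate:
    """Estimated substitution and indel error rates from a read sample."""

    eps_m_hat: float
    eps_g_hat: float
    n_used: int


@dataclass
class PEResult:
    """Selected parameter sets: (l, d, S1) tuples plus the cutting distance."""

    speed_set: Tuple[int, int, int]
    mapping_set: Tuple[int, int, int]
    ncd: float
    estimate: Optional[ErrorEstimate] = None


def hamming_budget(eps_m: float, l: int) -> int:
    """The PE distance rule d = floor(eps_m * l + 0.5)."""
    return math.floor(eps_m * l + 0.5)


def cutting_distance(est: Optional[ErrorEstimate] = None) -> float:
    """Normalized cutting distance: 5 * eps_g_hat, capped at 2; default 0.05."""
    if est is None:
        return 0.05
    return min(2.0, 5.0 * est.eps_g_hat)


def _column_counts(
    read: Read, genome: Genome, rec: AlignmentRecord
) -> Tuple[int, int, int, int]:
    """(mismatch, insertion, deletion, reference-consumed) column counts."""
    q = read.codes if rec.strand == FORWARD else revcomp_codes(read.codes)
    g = genome.codes
    qi = 0
    gi = rec.pos
    n_mm = n_ins = n_del = n_ref = 0
    for num, op in _CIGAR_RE.findall(rec.cigar):
        n = int(num)
        if op == "S":
            qi += n
        elif op == "M":
            seg_q = q[qi : qi + n]
            seg_g = g[gi : gi + n]
            n_mm += int(((seg_q != seg_g) | (seg_q == 4) | (seg_g == 4)).sum())
            qi += n
            gi += n
            n_ref += n
        elif op == "I":
            n_ins += n
            qi += n
        elif op == "D":
            n_del += n
            gi += n
            n_ref += n
    return n_mm, n_ins, n_del, n_ref


def _raw_rates(
    reads: Sequence[Read],
    genome: Genome,
    index: AnchorIndex,
    params: AlignParams,
    ncd_est: float,
    min_frac: float = 0.3,
) -> Tuple[float, float, int]:
    """Across-read mean mismatch and gap column rates of the anchored sample."""
    results, _ = anchor_reads(reads, index, params)
    reads_by_id = {r.id: r for r in reads}
    m_rates: List[float] = []
    g_rates: List[float] = []
    for rid, res in results.items():
        if res.status != ANCHORED:
            continue
        read = reads_by_id[rid]
        rec = local_align(
            read, genome, res.implied_start, res.strand, ncd_est, params.sw_scores
        )
        if rec is None or rec.score < min_frac * params.sw_match * read.length:
            continue
        n_mm, n_ins, n_del, n_ref = _column_counts(read, genome, rec)
        if n_ref == 0:
            continue
        m_rates.append(n_mm / n_ref)
        g_rates.append((n_ins + n_del) / n_ref)
    if not m_rates:
        raise ValueError("sample unanchorable; supply parameters manually")
    return float(np.mean(m_rates)), float(np.mean(g_rates)), len(m_rates)


def estimate_error_rates(
    reads: Sequence[Read],
    genome: Genome,
    index: Optional[AnchorIndex] = None,
    params: Optional[AlignParams] = None,
    seed: int = 0,
    ncd_est: float = 0.5,
    bias_correct: bool = True,
) -> ErrorEstimate:
    """Estimate (eps_m_hat, eps_g_hat) from a read sample.

    ``ncd_est`` sets a deliberately wide alignment band (the error rates
    are unknown at this point).  With ``bias_correct`` the parametric
    bootstrap correction described in the module docstring is applied.
    """
    if len(reads) < 1:
        raise ValueError("need at least one read to estimate from")
    if params is None:
        params = AlignParams(l1=PE_L, d1=PE_D, slide=0)
    if index is None:
        index = AnchorIndex(genome, params.l1, params.d1)
    m0, g0, n_used = _raw_rates(reads, genome, index, params, ncd_est)
    if not bias_correct or (m0 + g0) == 0.0:
        return ErrorEstimate(m0, g0, n_used)
    # parametric bootstrap: measure the counting bias of this very
    # procedure on reads simulated at the raw observed rates
    eps0 = min(m0 + g0, 0.95)
    model = ErrorModel(eps=eps0, mismatch_fraction=(m0 / eps0 if eps0 > 0 else 0.0))
    lengths = [r.length for r in reads]
    length = int(np.median(lengths))
    length = min(length, genome.length)
    boot_reads, _ = simulate_reads(
        genome, max(len(reads), 1), length, model, np.random.default_rng(seed),
        id_prefix="pe-boot",
    )
    try:
        m1, g1, _ = _raw_rates(boot_reads, genome, index, params, ncd_est)
    except ValueError:
        return ErrorEstimate(m0, g0, n_used)
    eps_m = min(max(m0 - (m1 - m0), 0.0), 0.999)
    eps_g = min(max(g0 - (g1 - g0), 0.0), 0.999)
    return ErrorEstimate(eps_m, eps_g, n_used)


def select_l_d(
    est: ErrorEstimate,
    reads: Sequence[Read],
    genome: Genome,
    candidate_ls: Sequence[int] = CANDIDATE_LS,
    rate_tolerance: float = 1.0,
) -> PEResult:
    """Choose (l, d) from the candidate set and emit both parameter sets.

    For each candidate l the sample is anchored with
    d = floor(eps_m_hat * l + 0.5); among candidates whose anchoring rate
    is within ``rate_tolerance`` percentage points of the maximum, the one
    with the lowest anchoring cost (candidate positions enumerated) wins.
    """
    if len(reads) < 1:
        raise ValueError("empty sample")
    stats: List[Tuple[int, int, float, int]] = []  # (l, d, rate, cost)
    for l in candidate_ls:
        d = hamming_budget(est.eps_m_hat, l)
        d = min(d, l - 1)
        if genome.length < l:
            continue
        index = AnchorIndex(genome, l, d)
        params = AlignParams(l1=l, d1=d, slide=0, l2=2 * l)
        results, _ = anchor_reads(reads, index, params)
        n_anch = sum(1 for r in results.values() if r.status == ANCHORED)
        rate = 100.0 * n_anch / len(reads)
        stats.append((l, d, rate, index.n_candidates))
    if not stats:
        raise ValueError("no candidate fragment length fits the genome")
    best_rate = max(s[2] for s in stats)
    eligible = [s for s in stats if s[2] >= best_rate - rate_tolerance]
    l, d, _, _ = min(eligible, key=lambda s: (s[3], s[0]))
    return PEResult(
        speed_set=(l, d, 0),
        mapping_set=(l, d + 1, max(1, round(l / 5))),
        ncd=cutting_distance(est),
        estimate=est,
    )
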
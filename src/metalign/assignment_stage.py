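"""Stage 2: candidate-position tables, exponential list-size weighting,
path construction/selection, and local-alignment verification.

Reads the anchoring stage could not place are cut into *overlapping*
fragments (stride l/2 by default) and every fragment is queried with a
capped candidate list; fragments whose list would exceed the cap are
discarded outright (they carry almost no positional information).  Each
surviving candidate position gets a raw score proportional to its match
quality and an exponentially down-weighted score S = S_a * exp(-0.5 |T|)
penalising large lists.  Mutually confirming candidates across fragments
are chained greedily into paths (this is the maximum-consensus search over
the per-fragment lists); the top-scoring paths within a fraction s_th of
the best are verified by banded local alignment, and surviving locations
are reported as a list (best first).  A second round with larger
fragments and a larger cap rescues reads from higher-copy repeats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core_index import (
    AlignParams,
    AnchorIndex,
    Genome,
    LOW_REPEAT,
    Read,
    UNIQUE,
)
from .alignment_stage import implied_start, local_align, positions_confirm
from .io import AlignmentRecord


@dataclass
class ScoredPosition:
    implied_start: int
    strand: str
    raw_score: float
    weighted_score: float
    fragment_index: int
    read_offset: int


@dataclass
class PositionTable:
    """Candidate list T_i(r) of one fragment (size <= the cap)."""

    fragment_index: int
    read_offset: int
    entries: List[ScoredPosition]


@dataclass
class Path:
    """A chain of mutually confirming candidate positions, one per fragment."""

    members: List[ScoredPosition]
    score: float
    consensus: int
    strand: str
    verified: Optional[AlignmentRecord] = None


def weight_score(raw: float, table_size: int) -> float:
    """Exponential list-size weighting S = S_a * exp(-0.5 |T|)."""
    if table_size < 1:
        raise ValueError("table size must be >= 1")
    return raw * math.exp(-0.5 * table_size)


def build_tables(
    read: Read,
    index: AnchorIndex,
    l: int,
    step: int,
    d: int,
    cap: int,
    match_weight: float = 1.0,
) -> List[PositionTable]:
    """Capped candidate tables for the overlapping fragments of a read.

    Fragments with an over-cap list are discarded; unmapped fragments
    produce no table.  Raw score S_a = (l - mismatches) * match_weight.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    L = read.length
    if L <= l:
        return []
    codes = read.codes
    tables: List[PositionTable] = []
    for i, off in enumerate(range(0, L - l + 1, step)):
        hl = index.query(codes[off : off + l], d=d, cap=cap)
        if hl.status not in (UNIQUE, LOW_REPEAT):
            continue
        size = len(hl.hits)
        entries = []
        for h in hl.hits:
            raw = (l - h.mismatches) * match_weight
            entries.append(
                ScoredPosition(
                    implied_start=implied_start(h.ref_pos, off, h.strand, L, l),
                    strand=h.strand,
                    raw_score=raw,
                    weighted_score=weight_score(raw, size),
                    fragment_index=i,
                    read_offset=off,
                )
            )
        entries.sort(key=lambda e: (e.implied_start, e.strand))
        tables.append(PositionTable(i, off, entries))
    return tables


def build_paths(tables: Sequence[PositionTable], params: AlignParams) -> List[Path]:
    """Greedy chaining of mutually confirming positions across tables.

    Scanning tables in order, each unconsumed position collects at most
    one (the best-weighted, leftmost on ties) unconsumed confirming
    partner from every later table; chains of >= 2 members become paths
    and their members are removed.  Positions that pair with nothing are
    dropped.  Paths are returned sorted by descending score, ties broken
    by leftmost consensus position.
    """
    consumed: List[List[bool]] = [[False] * len(t.entries) for t in tables]
    paths: List[Path] = []
    for ti, table in enumerate(tables):
        for pi, p in enumerate(table.entries):
            if consumed[ti][pi]:
                continue
            consumed[ti][pi] = True
            members = [p]
            for tj in range(ti + 1, len(tables)):
                best: Optional[Tuple[float, int, int]] = None
                for qi, q in enumerate(tables[tj].entries):
                    if consumed[tj][qi]:
                        continue
                    if positions_confirm(
                        p.implied_start, p.read_offset, p.strand,
                        q.implied_start, q.read_offset, q.strand,
                        params,
                    ):
                        key = (-q.weighted_score, q.implied_start, qi)
                        if best is None or key < best:
                            best = key
                if best is not None:
                    qi = best[2]
                    consumed[tj][qi] = True
                    members.append(tables[tj].entries[qi])
            if len(members) >= 2:
                starts = sorted(m.implied_start for m in members)
                consensus = int(starts[(len(starts) - 1) // 2])
                paths.append(
                    Path(
                        members=members,
                        score=sum(m.weighted_score for m in members),
                        consensus=consensus,
                        strand=p.strand,
                    )
                )
    paths.sort(key=lambda pa: (-pa.score, pa.consensus, pa.strand))
    return paths


def select_paths(paths: Sequence[Path], s_th: float) -> List[Path]:
    """Keep paths scoring at least s_th times the best path's score."""
    if not paths:
        return []
    cutoff = s_th * paths[0].score
    return [p for p in paths if p.score >= cutoff]


def verify_paths(
    read: Read,
    shortlist: Sequence[Path],
    genome: Genome,
    params: AlignParams,
    stage: str,
) -> List[AlignmentRecord]:
    """Locally align each selected path; drop low-scoring ones.

    A path survives when its banded-alignment score reaches
    min_score_frac of the perfect score (sw_match * L).  Survivors are
    reported best-first; the best is primary, the rest secondary.
    """
    threshold = params.min_score_frac * params.sw_match * read.length
    survivors: List[AlignmentRecord] = []
    for path in shortlist:
        rec = local_align(
            read, genome, path.consensus, path.strand,
            params.ncd, params.sw_scores, stage=stage,
        )
        if rec is not None and rec.score >= threshold:
            path.verified = rec
            survivors.append(rec)
    survivors.sort(key=lambda r: (-r.score, r.pos))
    for i, rec in enumerate(survivors):
        rec.is_secondary = i > 0
    return survivors


def assignment_round(
    reads: Sequence[Read],
    index: AnchorIndex,
    genome: Genome,
    l: int,
    step: int,
    d: int,
    cap: int,
    params: AlignParams,
    stage: str,
) -> Tuple[Dict[str, List[AlignmentRecord]], List[Read]]:
    """build_tables -> build_paths -> select_paths -> verify_paths per read.

    Returns reported record lists per read id and the reads still in R.
    """
    reported: Dict[str, List[AlignmentRecord]] = {}
    remaining: List[Read] = []
    for read in reads:
        tables = build_tables(read, index, l, step, d, cap, params.sw_match)
        recs: List[AlignmentRecord] = []
        if tables:
            paths = build_paths(tables, params)
            shortlist = select_paths(paths, params.s_th)
            recs = verify_paths(read, shortlist, genome, params, stage)
        if recs:
            reported[read.id] = recs
        else:
            remaining.append(read)
    return reported, remaining
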
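"""Synthetic data generation and alignment evaluation.

Two layers of randomness are modelled, matching the generative view of a
resequencing experiment:

* target-vs-reference variation: each reference base independently mutated
  with probability alpha (substitution : insertion : deletion = 2 : 1 : 1
  by default), producing the *target* genome the reads are drawn from;
* sequencing error: reads are substrings of the target (uniform start,
  uniform strand) whose bases are corrupted i.i.d. with total rate
  epsilon, split into a substitution share eps_m and an indel share eps_g
  (insertions and deletions equally likely, geometric lengths).

Error placement is i.i.d. per base rather than bursty; this is the harder
regime for fragment anchoring since errors are spread over all fragments.

The evaluator scores any SAM-style report against the simulation truth:
a read is correct when some reported location is on the true strand within
a slack (default: the read's own length) of the true start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .core_index import FORWARD, REVERSE, Genome, Read, decode, revcomp_codes


@dataclass
class ErrorModel:
    """Sequencing-error and target-variation rates.

    eps
        Total per-base sequencing error rate (0 <= eps < 1).
    mismatch_fraction
        Share of eps that is substitution; eps_m = eps * mismatch_fraction
        and eps_g = eps - eps_m.
    alpha
        Per-base target-vs-reference variation rate.
    indel_geometric_mean
        Mean indel length (geometric); 1 gives single-base indels.
    variant_split
        Relative weights of substitution : insertion : deletion for the
        target-variation process.
    """

    eps: float = 0.0
    mismatch_fraction: float = 0.5
    alpha: float = 0.0
    indel_geometric_mean: float = 1.0
    variant_split: Tuple[int, int, int] = (2, 1, 1)

    def __post_init__(self) -> None:
        if not (0.0 <= self.eps < 1.0):
            raise ValueError("eps must be in [0, 1)")
        if not (0.0 <= self.mismatch_fraction <= 1.0):
            raise ValueError("mismatch_fraction must be in [0, 1]")
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError("alpha must be in [0, 1)")
        if self.indel_geometric_mean < 1.0:
            raise ValueError("indel_geometric_mean must be >= 1")

    @property
    def eps_m(self) -> float:
        return self.eps * self.mismatch_fraction

    @property
    def eps_g(self) -> float:
        return self.eps - self.eps_m


@dataclass
class SimTruth:
    """Ground-truth record for one simulated read (0-based half-open)."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    n_sub: int = 0
    n_ins: int = 0
    n_del: int = 0


@dataclass
class EvalReport:
    """Recall/precision of an alignment report against simulation truth."""

    recall: float
    precision: float
    unique_rate: float
    n_reads: int
    n_reported: int
    n_correct: int


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_genome(length: int, seed, name: str = "synthetic") -> Genome:
    """An i.i.d. uniform ACGT genome of the given length."""
    rng = _rng(seed)
    codes = rng.integers(0, 4, size=length).astype(np.uint8)
    return Genome(name, decode(codes))


def genome_with_duplications(
    length: int,
    dup_fraction: float = 0.2,
    copies: Tuple[int, int] = (2, 5),
    unit_length: Tuple[int, int] = (1500, 4000),
    seed=0,
    name: str = "synthetic-dup",
) -> Tuple[Genome, List[Tuple[int, int]]]:
    """A random genome with planted low-copy duplications.

    Repeat units (uniform length in ``unit_length``) are generated once and
    inserted in ``copies`` identical copies until about ``dup_fraction`` of
    the final sequence is repeated content; the remainder is unique random
    sequence.  Blocks are shuffled before concatenation.  Returns the
    genome and the list of repeat-copy intervals (0-based half-open), so
    callers can split reads into repeat-interior and repeat-free subsets.
    """
    rng = _rng(seed)
    blocks: List[Tuple[np.ndarray, bool]] = []
    repeat_mass = 0
    target_repeat = dup_fraction * length
    total = 0
    while repeat_mass < target_repeat and total < length:
        ul = int(rng.integers(unit_length[0], unit_length[1] + 1))
        c = int(rng.integers(copies[0], copies[1] + 1))
        unit = rng.integers(0, 4, size=ul).astype(np.uint8)
        for _ in range(c):
            blocks.append((unit, True))
        repeat_mass += ul * c
        total += ul * c
    while total < length:
        ul = int(rng.integers(unit_length[0], unit_length[1] + 1))
        ul = min(ul, length - total)
        blocks.append((rng.integers(0, 4, size=ul).astype(np.uint8), False))
        total += ul
    order = rng.permutation(len(blocks))
    pieces = []
    intervals: List[Tuple[int, int]] = []
    pos = 0
    for bi in order:
        arr, is_rep = blocks[bi]
        if is_rep:
            intervals.append((pos, pos + arr.size))
        pieces.append(arr)
        pos += arr.size
    codes = np.concatenate(pieces)
    return Genome(name, decode(codes)), sorted(intervals)


class CoordinateMap:
    """Maps positions of a mutated target genome back to the reference.

    ``target_to_ref[t]`` is the reference index the target base ``t`` was
    copied from, or -1 for inserted bases.  ``to_ref`` resolves inserted
    bases to the next following reference base, so intervals translate
    cleanly; the round trip reference -> target -> reference is the
    identity everywhere outside deleted bases.
    """

    def __init__(self, target_to_ref: np.ndarray, ref_length: int):
        self.target_to_ref = target_to_ref
        self.ref_length = ref_length
        r2t = np.full(ref_length, -1, dtype=np.int64)
        src = target_to_ref >= 0
        r2t[target_to_ref[src]] = np.flatnonzero(src)
        self.ref_to_target = r2t

    def to_ref(self, target_pos: int) -> int:
        t2r = self.target_to_ref
        n = t2r.size
        p = target_pos
        while p < n and t2r[p] < 0:
            p += 1
        return int(t2r[p]) if p < n else self.ref_length

    def interval_to_ref(self, start: int, end: int) -> Tuple[int, int]:
        s = self.to_ref(start)
        e = self.to_ref(end - 1) + 1 if end > start else s
        return s, max(e, s)


def _geometric_lengths(rng: np.random.Generator, n: int, mean: float) -> np.ndarray:
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if mean <= 1.0:
        return np.ones(n, dtype=np.int64)
    return rng.geometric(1.0 / mean, size=n).astype(np.int64)


def _random_other_base(rng: np.random.Generator, base: int) -> int:
    r = int(rng.integers(0, 3))
    return r + 1 if r >= base else r  # uniform over the 3 others


def mutate_genome(
    reference: Genome, model: ErrorModel, seed
) -> Tuple[Genome, CoordinateMap]:
    """Plant alpha-rate variation into ``reference``, returning the target.

    Each base is independently mutated with probability alpha; the mutation
    type follows ``model.variant_split``.  Insertions place extra random
    bases after the mutated base; deletions drop it.
    """
    rng = _rng(seed)
    codes = reference.codes
    n = codes.size
    if model.alpha == 0.0:
        t2r = np.arange(n, dtype=np.int64)
        return (
            Genome(reference.name + "|target", reference.sequence),
            CoordinateMap(t2r, n),
        )
    sites = np.flatnonzero(rng.random(n) < model.alpha)
    w = np.asarray(model.variant_split, dtype=float)
    types = rng.choice(3, size=sites.size, p=w / w.sum())  # 0 sub, 1 ins, 2 del
    ins_lens = _geometric_lengths(rng, int((types == 1).sum()), model.indel_geometric_mean)
    pieces: List[np.ndarray] = []
    maps: List[np.ndarray] = []
    prev = 0
    ins_i = 0
    for pos, ty in zip(sites, types):
        pieces.append(codes[prev:pos])
        maps.append(np.arange(prev, pos, dtype=np.int64))
        if ty == 0:  # substitution
            pieces.append(np.array([_random_other_base(rng, int(codes[pos]))], dtype=np.uint8))
            maps.append(np.array([pos], dtype=np.int64))
        elif ty == 1:  # insertion after the base
            k = int(ins_lens[ins_i])
            ins_i += 1
            pieces.append(codes[pos : pos + 1])
            maps.append(np.array([pos], dtype=np.int64))
            pieces.append(rng.integers(0, 4, size=k).astype(np.uint8))
            maps.append(np.full(k, -1, dtype=np.int64))
        # ty == 2: deletion, emit nothing
        prev = pos + 1
    pieces.append(codes[prev:])
    maps.append(np.arange(prev, n, dtype=np.int64))
    target_codes = np.concatenate(pieces)
    t2r = np.concatenate(maps)
    return (
        Genome(reference.name + "|target", decode(target_codes)),
        CoordinateMap(t2r, n),
    )


def _apply_read_errors(
    template: np.ndarray, model: ErrorModel, rng: np.random.Generator
) -> Tuple[np.ndarray, int, int, int]:
    """Corrupt a template i.i.d. per base; returns (read codes, counts)."""
    L = template.size
    eps_m = model.eps_m
    eps_g = model.eps_g
    if model.eps == 0.0:
        return template.copy(), 0, 0, 0
    u = rng.random(L)
    sub = u < eps_m
    ins = (u >= eps_m) & (u < eps_m + 0.5 * eps_g)
    dele = (u >= eps_m + 0.5 * eps_g) & (u < eps_m + eps_g)
    events = np.flatnonzero(sub | ins | dele)
    ins_lens = _geometric_lengths(rng, int(ins.sum()), model.indel_geometric_mean)
    pieces: List[np.ndarray] = []
    prev = 0
    ins_i = 0
    for pos in events:
        pieces.append(template[prev:pos])
        if sub[pos]:
            pieces.append(
                np.array([_random_other_base(rng, int(template[pos]))], dtype=np.uint8)
            )
        elif ins[pos]:
            k = int(ins_lens[ins_i])
            ins_i += 1
            pieces.append(template[pos : pos + 1])
            pieces.append(rng.integers(0, 4, size=k).astype(np.uint8))
        # deletion: emit nothing
        prev = pos + 1
    pieces.append(template[prev:])
    read = np.concatenate(pieces)
    return read, int(sub.sum()), int(ins.sum()), int(dele.sum())


def simulate_reads(
    target: Genome,
    n: int,
    length: int,
    model: ErrorModel,
    seed,
    id_prefix: str = "read",
) -> Tuple[List[Read], List[SimTruth]]:
    """Draw ``n`` error-corrupted reads of template length ``length``.

    Start positions and strands are uniform; the truth interval is the
    template's location on ``target`` (0-based half-open).  The emitted
    read length may differ from ``length`` by the indel balance.
    """
    if n < 1:
        raise ValueError("need n >= 1 reads")
    if length > target.length:
        raise ValueError("read length exceeds target length")
    rng = _rng(seed)
    codes = target.codes
    starts = rng.integers(0, target.length - length + 1, size=n)
    strands = rng.integers(0, 2, size=n)
    reads: List[Read] = []
    truth: List[SimTruth] = []
    for i in range(n):
        s = int(starts[i])
        template = codes[s : s + length]
        strand = REVERSE if strands[i] else FORWARD
        if strand == REVERSE:
            template = revcomp_codes(template)
        out, n_sub, n_ins, n_del = _apply_read_errors(template, model, rng)
        rid = f"{id_prefix}{i:06d}"
        reads.append(Read(rid, decode(out), "I" * out.size))
        truth.append(
            SimTruth(rid, target.name, s, s + length, strand, n_sub, n_ins, n_del)
        )
    return reads, truth


def simulate_dataset(
    reference: Genome,
    model: ErrorModel,
    n: int,
    length: int,
    seed,
) -> Tuple[Genome, List[Read], List[SimTruth]]:
    """Mutate the reference at rate alpha, simulate reads from the target,
    and translate the truth intervals back to reference coordinates."""
    rng = _rng(seed)
    target, cmap = mutate_genome(reference, model, rng)
    reads, truth = simulate_reads(target, n, length, model, rng)
    for t in truth:
        t.chrom = reference.name
        t.start, t.end = cmap.interval_to_ref(t.start, t.end)
    return target, reads, truth


def evaluate(
    alignments: Iterable[Tuple[str, int, str]],
    truth: Sequence[SimTruth],
    slack: Optional[int] = None,
) -> EvalReport:
    """Score reported locations against the truth table.

    ``alignments`` yields (read_id, 0-based reference start, strand) for
    every reported location (primary and secondary).  A read is correct
    when any of its locations is on the true strand within ``slack`` bases
    (default: the read's template length) of the true start.  Recall is
    correct reads over all truth reads; precision is correct reads over
    reads with at least one reported location.
    """
    by_id: Dict[str, SimTruth] = {t.read_id: t for t in truth}
    locs: Dict[str, List[Tuple[int, str]]] = {}
    for rid, pos, strand in alignments:
        if rid not in by_id:
            raise KeyError(f"alignment for unknown read id {rid!r}")
        locs.setdefault(rid, []).append((pos, strand))
    n_reads = len(by_id)
    n_reported = len(locs)
    n_correct = 0
    n_unique = 0
    for rid, ll in locs.items():
        t = by_id[rid]
        sl = slack if slack is not None else (t.end - t.start)
        if len(ll) == 1:
            n_unique += 1
        if any(st == t.strand and abs(pos - t.start) <= sl for pos, st in ll):
            n_correct += 1
    return EvalReport(
        recall=100.0 * n_correct / n_reads if n_reads else 0.0,
        precision=100.0 * n_correct / n_reported if n_reported else 0.0,
        unique_rate=100.0 * n_unique / n_reads if n_reads else 0.0,
        n_reads=n_reads,
        n_reported=n_reported,
        n_correct=n_correct,
    )
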
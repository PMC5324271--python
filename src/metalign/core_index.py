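"""Sequence containers and the built-in l-mer anchoring index.

The index answers "where does this l-mer occur in the genome within Hamming
distance d, on either strand?" with a cap on the number of reported
positions.  It replaces an external short-read aligner for the fragment
anchoring and candidate-list construction steps.

Mechanism: pigeonhole seeding.  A query of length ``l`` allowed ``d``
mismatches is split into ``d + 1`` disjoint exact seeds of length
``l // (d + 1)``; any occurrence with at most ``d`` mismatches must contain
at least one exact seed, so exact seed lookups over a sorted genome k-mer
table enumerate a candidate superset that is then verified by a full
Hamming comparison.  This is exact for Hamming distance <= d.

Coordinates are 0-based half-open throughout; conversion to 1-based happens
only at SAM emission.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Optional, Sequence, Tuple

import numpy as np

FORWARD = "+"
REVERSE = "-"

# Base encoding: A=0 C=1 G=2 T=3, everything else (N and IUPAC ambiguity
# codes) = 4.  Code 4 mismatches every base including itself.
_LUT = np.full(256, 0xFF, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i
for _b in "NRYSWKMBDHVnryswkmbdhv":
    _LUT[ord(_b)] = 4

_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A,C,G,T -> 0..3; N/ambiguous -> 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _LUT[raw]
    if (codes == 0xFF).any():
        bad = chr(raw[int(np.argmax(codes == 0xFF))])
        raise ValueError(f"invalid base {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


@dataclass
class Genome:
    """A named reference sequence over {A, C, G, T, N} (stored upper-case)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("genome sequence must be non-empty")
        self.sequence = self.sequence.upper()

    @cached_property
    def codes(self) -> np.ndarray:
        return encode(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Read:
    """A sequenced read with optional per-base quality string."""

    id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.id}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    @cached_property
    def codes(self) -> np.ndarray:
        return encode(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class AlignParams:
    """Tunable parameters of the two-stage aligner.

    l1, d1
        Stage-1 fragment length and Hamming budget for anchoring.
    slide
        Sliding step S1 for overlapping stage-1 passes; 0 disables sliding
        (non-overlapping fragments only).
    l2, list_cap_2
        Second-round fragment length and candidate-list cap.
    list_cap_1
        Candidate-list cap for the first assignment round; fragments with
        more positions than the cap are discarded.
    ncd
        Normalized cutting distance: the banded local-alignment window and
        band half-width as a fraction of read length, in [0, 2].
    s_th
        Path retention fraction: paths scoring >= s_th * best are kept.
    confirm_slack_rate, confirm_delta_min
        Per-base indel allowance of the pairwise confirm rule; two same-
        strand tags confirm when their implied read-start positions differ
        by at most max(confirm_delta_min, ceil(rate * offset span)).
    sw_match, sw_mismatch, sw_gap
        Linear-gap Smith-Waterman scores.
    min_score_frac
        Verification filter: a path survives if its local-alignment score is
        at least this fraction of the perfect score (sw_match * L).
    n_t
        Sample size for parameter estimation.
    """

    l1: int = 25
    d1: int = 2
    slide: int = 0
    l2: int = 50
    list_cap_1: int = 10
    list_cap_2: int = 40
    ncd: float = 0.05
    s_th: float = 0.8
    confirm_slack_rate: float = 0.05
    confirm_delta_min: int = 3
    sw_match: int = 1
    sw_mismatch: int = -1
    sw_gap: int = -1
    min_score_frac: float = 0.5
    n_t: int = 10000

    def __post_init__(self) -> None:
        if not (self.l2 > self.l1 >= 1):
            raise ValueError("require l2 > l1 >= 1")
        if not (self.list_cap_2 >= self.list_cap_1 >= 1):
            raise ValueError("require list_cap_2 >= list_cap_1 >= 1")
        if not (0.0 <= self.ncd <= 2.0):
            raise ValueError("ncd must be in [0, 2]")
        if self.d1 < 0:
            raise ValueError("d1 must be >= 0")
        if not (0.0 < self.s_th <= 1.0):
            raise ValueError("s_th must be in (0, 1]")
        if self.slide < 0 or self.slide >= self.l1:
            if self.slide != 0:
                raise ValueError("slide must be 0 or in [1, l1)")

    @property
    def d2(self) -> int:
        """Round-2 Hamming budget, scaled with the fragment length."""
        return min(self.l2 - 1, round(self.d1 * self.l2 / self.l1))

    @property
    def sw_scores(self) -> Tuple[int, int, int]:
        return (self.sw_match, self.sw_mismatch, self.sw_gap)


@dataclass(frozen=True)
class LmerHit:
    """One genome occurrence of a queried l-mer."""

    ref_pos: int
    strand: str
    mismatches: int


UNMAPPED = "unmapped"
UNIQUE = "unique"
LOW_REPEAT = "low_repeat"
OVER_CAP = "over_cap"


@dataclass
class HitList:
    """Query result: hits sorted by (ref_pos, strand) plus a status label.

    unique     exactly one hit
    low_repeat 2..cap hits
    over_cap   more hits than the cap; enumeration stopped, hits is empty
    unmapped   no hit within the budget
    """

    hits: Tuple[LmerHit, ...]
    status: str


class AnchorIndex:
    """Hamming-distance l-mer index over one genome.

    Built for a fixed fragment length ``l`` and maximum budget ``d``;
    queries may use any budget <= d.  Counters ``n_queries`` and
    ``n_candidates`` track index work (used as the hardware-independent
    anchoring-cost proxy during parameter selection).
    """

    _FORMAT_VERSION = 1

    def __init__(self, genome: Genome, l: int, d: int):
        if l < 1:
            raise ValueError("fragment length must be >= 1")
        if d < 0:
            raise ValueError("Hamming budget must be >= 0")
        if genome.length < l:
            raise ValueError("genome too short")
        if d >= l:
            raise ValueError("distance exceeds length")
        self.genome = genome
        self.l = l
        self.d = d
        self.seed_len = max(1, l // (d + 1))
        self.n_queries = 0
        self.n_candidates = 0
        self._codes = genome.codes
        self._build()

    # -- construction -----------------------------------------------------

    def _build(self) -> None:
        codes = self._codes
        n = codes.size
        k = self.seed_len
        m = n - k + 1
        # Rolling multiply-by-4 hash in uint64 (wraparound for k > 32 only
        # produces extra candidates, never misses: verification filters).
        h = np.zeros(m, dtype=np.uint64)
        has_n = np.zeros(m, dtype=bool)
        four = np.uint64(4)
        with np.errstate(over="ignore"):  # uint64 wraparound is intended
            for j in range(k):
                col = codes[j : j + m]
                h = h * four + col.astype(np.uint64)
                has_n |= col == 4
        valid = np.flatnonzero(~has_n)
        hv = h[valid]
        order = np.argsort(hv, kind="stable")
        self._hashes = hv[order]
        self._positions = valid[order].astype(np.int64)

    def _hash_seed(self, seed: np.ndarray) -> np.uint64:
        h = np.uint64(0)
        four = np.uint64(4)
        with np.errstate(over="ignore"):  # uint64 wraparound is intended
            for c in seed:
                h = h * four + np.uint64(c)
        return h

    # -- querying ---------------------------------------------------------

    def _candidate_starts(self, q: np.ndarray) -> np.ndarray:
        """Candidate start offsets of q on the forward genome strand."""
        k = self.seed_len
        n = self._codes.size
        parts = []
        for i in range(self.d + 1):
            lo_off = i * k
            if lo_off + k > q.size:
                break
            seed = q[lo_off : lo_off + k]
            if (seed == 4).any():
                continue  # a seed containing N never matches exactly
            h = self._hash_seed(seed)
            lo = int(np.searchsorted(self._hashes, h, side="left"))
            hi = int(np.searchsorted(self._hashes, h, side="right"))
            if hi > lo:
                parts.append(self._positions[lo:hi] - lo_off)
        if not parts:
            return np.empty(0, dtype=np.int64)
        cand = np.unique(np.concatenate(parts))
        return cand[(cand >= 0) & (cand <= n - q.size)]

    def _verify(self, q: np.ndarray, cand: np.ndarray, d: int):
        """Hamming-verify candidates; N mismatches everything."""
        if cand.size == 0:
            return cand, np.empty(0, dtype=np.int64)
        self.n_candidates += int(cand.size)
        win = self._codes[cand[:, None] + np.arange(q.size)]
        mm = ((win != q) | (win == 4) | (q == 4)).sum(axis=1)
        keep = mm <= d
        return cand[keep], mm[keep].astype(np.int64)

    def query(self, s, d: Optional[int] = None, cap: int = 1) -> HitList:
        """All genome positions of ``s`` (both strands) within Hamming ``d``.

        Reverse-strand hits are occurrences of the reverse complement of
        ``s`` on the forward strand, reported with that forward position.
        Returns status ``over_cap`` with an empty hit tuple as soon as the
        count exceeds ``cap``.
        """
        if d is None:
            d = self.d
        if d > self.d:
            raise ValueError(f"query budget {d} exceeds index budget {self.d}")
        if cap < 1:
            raise ValueError("cap must be >= 1")
        q = encode(s) if isinstance(s, str) else np.asarray(s, dtype=np.uint8)
        if q.size != self.l:
            raise ValueError(f"query length {q.size} != index fragment length {self.l}")
        self.n_queries += 1

        fpos, fmm = self._verify(q, self._candidate_starts(q), d)
        if fpos.size > cap:
            return HitList((), OVER_CAP)
        rc = revcomp_codes(q)
        rpos, rmm = self._verify(rc, self._candidate_starts(rc), d)
        total = fpos.size + rpos.size
        if total > cap:
            return HitList((), OVER_CAP)
        if total == 0:
            return HitList((), UNMAPPED)

        hits = [LmerHit(int(p), FORWARD, int(m)) for p, m in zip(fpos, fmm)]
        hits += [LmerHit(int(p), REVERSE, int(m)) for p, m in zip(rpos, rmm)]
        hits.sort(key=lambda h: (h.ref_pos, h.strand))
        status = UNIQUE if total == 1 else LOW_REPEAT
        return HitList(tuple(hits), status)

    def reset_counters(self) -> None:
        self.n_queries = 0
        self.n_candidates = 0

    # -- optional on-disk serialization (private versioned format) --------

    def save(self, path) -> None:
        np.savez(
            path,
            version=np.int64(self._FORMAT_VERSION),
            l=np.int64(self.l),
            d=np.int64(self.d),
            name=np.bytes_(self.genome.name.encode()),
            codes=self._codes,
            hashes=self._hashes,
            positions=self._positions,
        )

    @classmethod
    def load(cls, path) -> "AnchorIndex":
        with np.load(path) as z:
            if int(z["version"]) != cls._FORMAT_VERSION:
                raise ValueError("unsupported index format version")
            genome = Genome(bytes(z["name"]).decode(), decode(z["codes"]))
            idx = cls.__new__(cls)
            idx.genome = genome
            idx.l = int(z["l"])
            idx.d = int(z["d"])
            idx.seed_len = max(1, idx.l // (idx.d + 1))
            idx.n_queries = 0
            idx.n_candidates = 0
            idx._codes = genome.codes
            idx._hashes = z["hashes"].copy()
            idx._positions = z["positions"].copy()
        return idx


def build_index(genome: Genome, l: int, d: int) -> AnchorIndex:
    """Build an :class:`AnchorIndex` over ``genome`` for (l, d) queries."""
    return AnchorIndex(genome, l, d)
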
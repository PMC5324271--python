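"""File formats: FASTA/FASTQ input (optionally gzipped), SAM output via
pysam, and the BED-like truth / evaluation TSV tables."""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import pysam
from Bio import SeqIO

from .core_index import FORWARD, Genome, Read, REVERSE, revcomp


@dataclass
class AlignmentRecord:
    """One reported location for a read (0-based position internally)."""

    read_id: str
    ref_name: str
    pos: int  # 0-based leftmost reference position
    strand: str
    cigar: str
    score: int
    is_secondary: bool = False
    stage: str = "stage1"
    mapped: bool = True


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def cigar_read_span(cigar: str) -> Tuple[int, int]:
    """(read bases consumed incl. soft clips, reference bases consumed)."""
    read_n = 0
    ref_n = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        if op in "MIS=X":
            read_n += n
        if op in "MDN=X":
            ref_n += n
    return read_n, ref_n


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> Iterator[Genome]:
    """Stream Genome records from a (possibly gzipped) FASTA file."""
    with _open_text(path) as fh:
        n = 0
        for rec in SeqIO.parse(fh, "fasta"):
            n += 1
            yield Genome(rec.id, str(rec.seq))
        if n == 0:
            raise ValueError(f"{path}: no FASTA records found")


def read_fastq(path) -> Iterator[Read]:
    """Stream Read records from a (possibly gzipped) FASTQ file."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield Read(rec.id, str(rec.seq), qual)


def read_sequences(path) -> Iterator[Read]:
    """Reads from FASTA or FASTQ, sniffed from the first character."""
    with _open_text(path) as fh:
        first = fh.read(1)
    if first == ">":
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                yield Read(rec.id, str(rec.seq))
    else:
        yield from read_fastq(path)


def write_fastq(reads: Iterable[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.quality if r.quality is not None else "I" * r.length
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def write_fasta(genomes: Iterable[Genome], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.name}\n")
            for i in range(0, g.length, width):
                fh.write(g.sequence[i : i + width] + "\n")


# -- truth table (BED-like TSV) ------------------------------------------

TRUTH_COLUMNS = ("read_id", "chrom", "start", "end", "strand", "n_sub", "n_ins", "n_del")


def write_truth(truth, path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(TRUTH_COLUMNS) + "\n")
        for t in truth:
            fh.write(
                f"{t.read_id}\t{t.chrom}\t{t.start}\t{t.end}\t{t.strand}"
                f"\t{t.n_sub}\t{t.n_ins}\t{t.n_del}\n"
            )


def read_truth(path):
    from .read_sim import SimTruth

    out = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 5:
                raise ValueError(f"{path}:{ln}: truth row needs >= 5 columns")
            out.append(
                SimTruth(
                    f[0], f[1], int(f[2]), int(f[3]), f[4],
                    *(int(x) for x in f[5:8]),
                )
            )
    return out


# -- SAM ------------------------------------------------------------------


def write_sam(
    records: Sequence[AlignmentRecord],
    reads_by_id: Dict[str, Read],
    references: Sequence[Genome],
    path,
) -> None:
    """Emit a valid SAM file (flags 0/16 strand, 256 secondary, 4 unmapped).

    All records are validated (CIGAR consumes the read length, reference
    span inside the reference) before anything is written.
    """
    ref_ids = {g.name: i for i, g in enumerate(references)}
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": g.name, "LN": g.length} for g in references],
        }
    )
    segments = []
    for rec in records:
        read = reads_by_id[rec.read_id]
        seg = pysam.AlignedSegment(header)
        seg.query_name = rec.read_id
        if not rec.mapped:
            seg.flag = 4
            seg.reference_id = -1
            seg.reference_start = -1
            seg.mapping_quality = 0
            seg.query_sequence = read.sequence
            if read.quality:
                seg.query_qualities = pysam.qualitystring_to_array(read.quality)
            segments.append(seg)
            continue
        if rec.ref_name not in ref_ids:
            raise ValueError(f"record references unknown sequence {rec.ref_name!r}")
        read_n, ref_n = cigar_read_span(rec.cigar)
        if read_n != read.length:
            raise ValueError(
                f"{rec.read_id}: CIGAR {rec.cigar} consumes {read_n} bases, "
                f"read has {read.length}"
            )
        ref_len = references[ref_ids[rec.ref_name]].length
        if rec.pos < 0 or rec.pos + ref_n > ref_len:
            raise ValueError(f"{rec.read_id}: alignment outside reference bounds")
        flag = 0
        if rec.strand == REVERSE:
            flag |= 16
        if rec.is_secondary:
            flag |= 256
        seg.flag = flag
        seg.reference_id = ref_ids[rec.ref_name]
        seg.reference_start = rec.pos
        seg.mapping_quality = 0 if rec.is_secondary else 60
        seg.cigarstring = rec.cigar
        seq = read.sequence if rec.strand == FORWARD else revcomp(read.sequence)
        seg.query_sequence = seq
        if read.quality:
            qual = read.quality if rec.strand == FORWARD else read.quality[::-1]
            seg.query_qualities = pysam.qualitystring_to_array(qual)
        seg.set_tag("AS", rec.score)
        seg.set_tag("XT", rec.stage)
        segments.append(seg)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for seg in segments:
            out.write(seg)


def read_sam_locations(path) -> List[Tuple[str, int, str]]:
    """(read_id, 0-based position, strand) for every mapped SAM record."""
    out: List[Tuple[str, int, str]] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for seg in sam:
            if seg.is_unmapped:
                continue
            strand = REVERSE if seg.is_reverse else FORWARD
            out.append((seg.query_name, seg.reference_start, strand))
    return out
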
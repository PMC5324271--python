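"""Pipeline driver: optional parameter estimation, stage 1 anchoring,
two assignment rounds, SAM emission and a run summary.

The partition contract: every input read ends up in exactly one of
stage1-anchored, stage2-round1, stage2-round2 or unaligned.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .core_index import AlignParams, AnchorIndex, Genome, Read
from .alignment_stage import ANCHORED, AMBIGUOUS, align_anchored, anchor_reads
from .assignment_stage import assignment_round
from .io import (
    AlignmentRecord,
    read_fasta,
    read_sequences,
    write_sam,
)
from .param_estimation import PEResult, estimate_error_rates, select_l_d

SPEED = "speed"
MAPPING = "mapping"


@dataclass
class PipelineResult:
    records: List[AlignmentRecord]
    summary: Dict[str, object]
    params: AlignParams
    pe: Optional[PEResult] = None


def _apply_pe(params: AlignParams, pe: PEResult, priority: str) -> AlignParams:
    l, d, s1 = pe.mapping_set if priority == MAPPING else pe.speed_set
    return dataclasses.replace(
        params,
        l1=l,
        d1=d,
        slide=s1,
        l2=2 * l,
        ncd=pe.ncd,
        confirm_slack_rate=max(0.05, 2.0 * pe.estimate.eps_g_hat),
    )


def align_reads(
    genome: Genome,
    reads: Sequence[Read],
    params: Optional[AlignParams] = None,
    estimate: bool = False,
    priority: str = MAPPING,
    seed: int = 0,
    select_sample_size: int = 200,
) -> PipelineResult:
    """Run the full two-stage aligner on in-memory inputs.

    With ``estimate`` the PE algorithm runs on the first n_t reads and the
    chosen parameter set (speed- or mapping-priority) overrides l1/d1/S1,
    the cutting distance and the confirm slack.
    """
    params = params if params is not None else AlignParams()
    reads = list(reads)
    pe: Optional[PEResult] = None
    if estimate and reads:
        sample = reads[: params.n_t]
        est = estimate_error_rates(sample, genome, seed=seed)
        pe = select_l_d(est, sample[:select_sample_size], genome)
        params = _apply_pe(params, pe, priority)

    reads_by_id = {r.id: r for r in reads}
    records: List[AlignmentRecord] = []
    summary: Dict[str, object] = {"n_reads": len(reads)}

    # stage 1: anchoring + banded local alignment
    index1 = AnchorIndex(genome, params.l1, params.d1)
    results, remaining = anchor_reads(reads, index1, params)
    demoted = align_anchored(results, reads_by_id, genome, params)
    remaining = remaining + [reads_by_id[rid] for rid in demoted]
    stage1_ids = [
        rid for rid, res in results.items() if res.status == ANCHORED
    ]
    for rid in stage1_ids:
        records.append(results[rid].alignment)
    summary["stage1_anchored"] = len(stage1_ids)
    summary["stage1_ambiguous"] = sum(
        1 for res in results.values() if res.status == AMBIGUOUS
    )

    # stage 2, round 1: same fragment length, capped lists
    step1 = max(1, params.l1 // 2)
    reported1, remaining = assignment_round(
        remaining, index1, genome, params.l1, step1, params.d1,
        params.list_cap_1, params, stage="stage2-round1",
    )
    for recs in reported1.values():
        records.extend(recs)
    summary["stage2_round1"] = len(reported1)

    # stage 2, round 2: larger fragments, larger cap
    reported2: Dict[str, List[AlignmentRecord]] = {}
    if remaining and genome.length >= params.l2:
        index2 = AnchorIndex(genome, params.l2, params.d2)
        step2 = max(1, params.l2 // 2)
        reported2, remaining = assignment_round(
            remaining, index2, genome, params.l2, step2, params.d2,
            params.list_cap_2, params, stage="stage2-round2",
        )
        for recs in reported2.values():
            records.extend(recs)
    summary["stage2_round2"] = len(reported2)

    # pass-through for unaligned reads
    for read in remaining:
        records.append(
            AlignmentRecord(
                read_id=read.id, ref_name=genome.name, pos=0, strand="+",
                cigar="*", score=0, mapped=False, stage="unaligned",
            )
        )
    summary["unaligned"] = len(remaining)

    n_mapped = len(reads) - len(remaining)
    per_read: Dict[str, int] = {}
    for rec in records:
        if rec.mapped:
            per_read[rec.read_id] = per_read.get(rec.read_id, 0) + 1
    summary["mapped_pct"] = 100.0 * n_mapped / len(reads) if reads else 0.0
    summary["unique_pct"] = (
        100.0 * sum(1 for v in per_read.values() if v == 1) / len(reads)
        if reads
        else 0.0
    )
    summary["params"] = (
        f"l1={params.l1},d1={params.d1},slide={params.slide},l2={params.l2},"
        f"d2={params.d2},cap1={params.list_cap_1},cap2={params.list_cap_2},"
        f"ncd={params.ncd:g},s_th={params.s_th:g},"
        f"slack={params.confirm_slack_rate:g}"
    )
    return PipelineResult(records=records, summary=summary, params=params, pe=pe)


def run_pipeline(
    reference_path,
    reads_path,
    sam_path,
    summary_path=None,
    params: Optional[AlignParams] = None,
    estimate: bool = False,
    priority: str = MAPPING,
    seed: int = 0,
) -> PipelineResult:
    """File-based front end: FASTA reference + FASTA/FASTQ reads -> SAM.

    A multi-record reference FASTA is not supported: alignment runs
    against the first record.
    """
    genomes = list(read_fasta(reference_path))
    genome = genomes[0]
    reads = list(read_sequences(reads_path))
    result = align_reads(
        genome, reads, params=params, estimate=estimate,
        priority=priority, seed=seed,
    )
    reads_by_id = {r.id: r for r in reads}
    write_sam(result.records, reads_by_id, [genome], sam_path)
    if summary_path is not None:
        write_summary(result.summary, summary_path)
    return result


def write_summary(summary: Dict[str, object], path) -> None:
    with open(path, "w") as fh:
        for k, v in summary.items():
            if isinstance(v, float):
                fh.write(f"{k}\t{v:.4f}\n")
            else:
                fh.write(f"{k}\t{v}\n")


# -- flat key=value parameter files (output of `metalign estimate`) -------

_FLOAT_PARAMS = {"ncd", "s_th", "confirm_slack_rate", "min_score_frac"}
_PARAM_KEYS = {f.name for f in dataclasses.fields(AlignParams)}
_EXTRA_KEYS = {"eps_m_hat", "eps_g_hat"}


def write_params_file(params: AlignParams, path, extra: Optional[Dict] = None) -> None:
    with open(path, "w") as fh:
        for f in dataclasses.fields(AlignParams):
            fh.write(f"{f.name}={getattr(params, f.name)!r}\n".replace("'", ""))
        for k, v in (extra or {}).items():
            fh.write(f"{k}={v}\n")


def read_params_file(path) -> AlignParams:
    values: Dict[str, object] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected key=value")
            k, v = line.split("=", 1)
            k = k.strip()
            if k in _EXTRA_KEYS:
                continue
            if k not in _PARAM_KEYS:
                raise ValueError(f"{path}:{ln}: unknown parameter {k!r}")
            v = v.strip()
            values[k] = float(v) if k in _FLOAT_PARAMS else int(v)
    return AlignParams(**values)
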
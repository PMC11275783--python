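"""Simple tandem-duplication calling from allele-specific copy-number
segments.

A segment is called a simple TD when (i) it is shorter than 10 Mb,
(ii) both flanking segments on the same chromosome arm have strictly
lower total copy number, and (iii) the two flanking copy numbers differ
by at most 1. The first/last segment of an arm lacks a flank and never
qualifies. In WGS mode candidate calls are additionally intersected
with tandem-duplication-typed SV breakpoints.
"""
from __future__ import annotations

from typing import Iterable, Optional

from .model import (
    CopyNumberSegment,
    GenomicInterval,
    SVEvent,
    TandemDuplication,
    sort_segments,
)

DEFAULT_MAX_TD_LENGTH = 10_000_000  # bp, strict upper bound
DEFAULT_BREAKPOINT_TOL = 10_000  # bp, bin-scale matching tolerance


def _arm_key(seg: CopyNumberSegment, arms: Optional[list]) -> tuple:
    """Arm identity used to decide adjacency; falls back to whole
    chromosome when no arm definitions are supplied."""
    if arms:
        for arm in arms:
            if arm.chrom == seg.chrom and arm.overlap(seg.chrom, seg.start, seg.end) > 0:
                return (seg.chrom, arm.name)
    return (seg.chrom, "")


def call_simple_tds(
    segments: Iterable[CopyNumberSegment],
    max_len: int = DEFAULT_MAX_TD_LENGTH,
    arms: Optional[list] = None,
) -> list[TandemDuplication]:
    """Return the segments satisfying all three TD criteria.

    ``segments`` must be non-overlapping within each chromosome (raises
    otherwise). ``arms`` (role=arm :class:`GenomicInterval` list) bounds
    adjacency: segments abutting a centromere lack that flank.
    """
    segs = sort_segments(segments)
    by_arm: dict[tuple, list] = {}
    for seg in segs:
        by_arm.setdefault(_arm_key(seg, arms), []).append(seg)

    calls = []
    for run in by_arm.values():
        for left, mid, right in zip(run, run[1:], run[2:]):
            if mid.length >= max_len:
                continue
            if not (mid.total_cn > left.total_cn and mid.total_cn > right.total_cn):
                continue
            if abs(left.total_cn - right.total_cn) > 1:
                continue
            calls.append(
                TandemDuplication(
                    chrom=mid.chrom,
                    start=mid.start,
                    end=mid.end,
                    segment_cn=mid.total_cn,
                    left_flank_cn=left.total_cn,
                    right_flank_cn=right.total_cn,
                )
            )
    calls.sort(key=lambda t: (t.chrom, t.start))
    return calls


def intersect_tds_with_sv(
    candidates: Iterable[TandemDuplication],
    svs: Iterable[SVEvent],
    tol: int = DEFAULT_BREAKPOINT_TOL,
    require_both_ends: bool = True,
) -> list[TandemDuplication]:
    """WGS mode: keep candidates whose endpoints match the breakpoints
    of some tandem-duplication-typed SV within ``tol`` bp.

    With ``require_both_ends`` both candidate endpoints must match the
    two breakpoints of a single SV; otherwise one matching end suffices.
    """
    td_svs = [
        sv
        for sv in svs
        if sv.sv_type == "tandem_duplication" and sv.intrachromosomal
    ]
    kept = []
    for cand in candidates:
        for sv in td_svs:
            if sv.bp1.chrom != cand.chrom:
                continue
            lo, hi = sorted((sv.bp1.pos, sv.bp2.pos))
            start_hit = abs(cand.start - lo) <= tol
            end_hit = abs(cand.end - hi) <= tol
            ok = (start_hit and end_hit) if require_both_ends else (start_hit or end_hit)
            if ok:
                kept.append(cand)
                break
    return kept


def write_td_calls(path, tds: Iterable[TandemDuplication]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tlength\tsegment_cn\tleft_flank_cn\tright_flank_cn\n")
        for td in tds:
            fh.write(
                f"{td.chrom}\t{td.start}\t{td.end}\t{td.length}\t"
                f"{td.segment_cn}\t{td.left_flank_cn}\t{td.right_flank_cn}\n"
            )
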
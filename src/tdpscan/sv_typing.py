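"""Structural-variant classification from breakpoint orientations and
bin-level copy number.

Inter-chromosomal events are translocations. Intra-chromosomal events
with span <= 1 kb are removed upstream; the remainder are classified by
the junction orientations and the 10 kb-bin copy numbers around and
between the breakpoints:

* ``(+, -)`` with interior mean below both outer flanks -> deletion
* ``(-, +)`` with interior mean above both outer flanks -> tandem duplication
* ``(+, +)`` / ``(-, -)`` -> inversion
* otherwise balanced (all defined flanking values equal) or unbalanced

When flanking copy numbers are undefined (coverage gaps), orientation
alone decides between deletion/tandem duplication.
"""
from __future__ import annotations

import math
from typing import Iterable, Optional

import numpy as np

from .model import CopyNumberSegment, SVEvent

BIN_SIZE = 10_000  # bp
MIN_SV_SPAN = 1_000  # bp, strict: span must exceed this to be retained
LONG_SPAN = 10_000_000  # bp; balanced/unbalanced above this act translocation-like


class CopyNumberBins:
    """10 kb-bin copy-number track per chromosome. Bins with no data are
    NaN and yield undefined c-values."""

    def __init__(self, values_by_chrom: dict, bin_size: int = BIN_SIZE):
        self.bin_size = bin_size
        self.values = {c: np.asarray(v, dtype=float) for c, v in values_by_chrom.items()}

    @classmethod
    def from_segments(
        cls,
        segments: Iterable[CopyNumberSegment],
        chrom_lengths: dict,
        bin_size: int = BIN_SIZE,
    ) -> "CopyNumberBins":
        """Rasterise segments onto bins; a bin takes the copy number of
        the segment covering its midpoint (NaN when uncovered)."""
        values = {
            c: np.full(int(math.ceil(length / bin_size)), np.nan)
            for c, length in chrom_lengths.items()
        }
        for seg in segments:
            arr = values.get(seg.chrom)
            if arr is None:
                continue
            first = (seg.start - 1) // bin_size
            last = (seg.end - 1) // bin_size
            for i in range(first, min(last + 1, len(arr))):
                mid = i * bin_size + bin_size // 2 + 1
                if seg.start <= mid <= seg.end:
                    arr[i] = seg.total_cn
        return cls(values, bin_size)

    def bin_value(self, chrom: str, bin_index: int) -> Optional[float]:
        arr = self.values.get(chrom)
        if arr is None or not 0 <= bin_index < len(arr):
            return None
        v = arr[bin_index]
        return None if math.isnan(v) else float(v)

    def value_at(self, chrom: str, pos: int) -> Optional[float]:
        return self.bin_value(chrom, (pos - 1) // self.bin_size)

    def mean_between(self, chrom: str, pos1: int, pos2: int) -> Optional[float]:
        """Mean copy number of the bins strictly between two positions
        (bins containing the breakpoints themselves are excluded)."""
        lo, hi = sorted((pos1, pos2))
        first = (lo - 1) // self.bin_size + 1
        last = (hi - 1) // self.bin_size - 1
        vals = [self.bin_value(chrom, i) for i in range(first, last + 1)]
        vals = [v for v in vals if v is not None]
        if not vals:
            return None
        return float(np.mean(vals))


def filter_svs_by_span(svs: Iterable[SVEvent], min_span: int = MIN_SV_SPAN):
    """Drop intra-chromosomal events with span <= ``min_span`` (1 kb)."""
    return [sv for sv in svs if not sv.intrachromosomal or sv.span > min_span]


def annotate_breakpoint_cn(sv: SVEvent, bins: CopyNumberBins) -> SVEvent:
    """Populate c1_up/c1_down/c2_up/c2_down and (intra-chromosomal)
    c_mean from the bins flanking each breakpoint."""
    b = bins.bin_size
    i1 = (sv.bp1.pos - 1) // b
    i2 = (sv.bp2.pos - 1) // b
    sv.c1_up = bins.bin_value(sv.bp1.chrom, i1 - 1)
    sv.c1_down = bins.bin_value(sv.bp1.chrom, i1 + 1)
    sv.c2_up = bins.bin_value(sv.bp2.chrom, i2 - 1)
    sv.c2_down = bins.bin_value(sv.bp2.chrom, i2 + 1)
    if sv.intrachromosomal:
        sv.c_mean = bins.mean_between(sv.bp1.chrom, sv.bp1.pos, sv.bp2.pos)
    return sv


def classify_sv(sv: SVEvent) -> str:
    """Assign exactly one SV class (total over retained events); stores
    and returns the label."""
    if not sv.intrachromosomal:
        sv.sv_type = "translocation"
        return sv.sv_type

    # order breakpoints along the chromosome
    if sv.bp1.pos <= sv.bp2.pos:
        left, right = sv.bp1, sv.bp2
        c_left_up, c_right_down = sv.c1_up, sv.c2_down
    else:
        left, right = sv.bp2, sv.bp1
        c_left_up, c_right_down = sv.c2_up, sv.c1_down
    orient = (left.orientation, right.orientation)

    flanks = [c for c in (c_left_up, c_right_down) if c is not None]
    cm = sv.c_mean

    if orient == ("+", "-"):
        if cm is None or not flanks:
            sv.sv_type = "deletion"  # orientation-only fallback at coverage gaps
        elif cm < min(flanks):
            sv.sv_type = "deletion"
        else:
            sv.sv_type = _balanced_or_unbalanced(sv)
    elif orient == ("-", "+"):
        if cm is None or not flanks:
            sv.sv_type = "tandem_duplication"
        elif cm > max(flanks):
            sv.sv_type = "tandem_duplication"
        else:
            sv.sv_type = _balanced_or_unbalanced(sv)
    elif orient in (("+", "+"), ("-", "-")):
        sv.sv_type = "inversion"
    else:  # unreachable with validated orientations
        raise ValueError(f"missing orientation on {sv}")
    return sv.sv_type


def _balanced_or_unbalanced(sv: SVEvent) -> str:
    defined = [c for c in (sv.c1_up, sv.c1_down, sv.c2_up, sv.c2_down) if c is not None]
    if defined and all(c == defined[0] for c in defined):
        return "balanced_intra"
    return "unbalanced_intra"


def classify_all(svs: Iterable[SVEvent], bins: Optional[CopyNumberBins] = None,
                 min_span: int = MIN_SV_SPAN) -> list[SVEvent]:
    """Span-filter, optionally annotate copy number, and classify."""
    retained = filter_svs_by_span(svs, min_span)
    for sv in retained:
        if bins is not None:
            annotate_breakpoint_cn(sv, bins)
        classify_sv(sv)
    return retained


def is_translocation_like(sv: SVEvent, long_span: int = LONG_SPAN) -> bool:
    """Events treated like translocations for gene-flanking logic:
    inter-chromosomal, or balanced/unbalanced spanning > 10 Mb."""
    if sv.sv_type == "translocation":
        return True
    return (
        sv.sv_type in ("balanced_intra", "unbalanced_intra")
        and sv.span is not None
        and sv.span > long_span
    )
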
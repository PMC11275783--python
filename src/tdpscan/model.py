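"""Shared data model for tumor-genome profiles.

All internal coordinates are 1-based inclusive (SEG convention). BEDPE and
BED files are converted at the IO boundary (see :mod:`tdpscan.io`).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "CopyNumberSegment",
    "SVBreakpoint",
    "SVEvent",
    "VariantCall",
    "GenomicInterval",
    "TandemDuplication",
    "TumorProfile",
    "SV_TYPES",
]

#: recognised structural-variant classes
SV_TYPES = (
    "deletion",
    "tandem_duplication",
    "inversion",
    "balanced_intra",
    "unbalanced_intra",
    "translocation",
)


@dataclass(frozen=True)
class CopyNumberSegment:
    """Allele-specific copy-number interval.

    ``minor_cn`` is the lower parental allele count; ``minor_cn == 0``
    marks loss of heterozygosity. ``cellular_fraction`` is the estimated
    fraction of tumor cells carrying the event (1.0 = clonal).
    """

    chrom: str
    start: int
    end: int
    total_cn: int
    minor_cn: int
    cellular_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"segment {self.chrom}:{self.start}-{self.end}: start > end"
            )
        if self.total_cn < 0 or self.minor_cn < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.minor_cn > self.total_cn:
            raise ValueError(
                f"minor_cn {self.minor_cn} exceeds total_cn {self.total_cn}"
            )
        if not 0.0 <= self.cellular_fraction <= 1.0:
            raise ValueError("cellular_fraction must be in [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_loh(self) -> bool:
        return self.minor_cn == 0 and self.total_cn > 0


@dataclass(frozen=True)
class SVBreakpoint:
    """One end of a rearrangement junction.

    ``orientation`` is the direction the joined fragment extends from the
    breakpoint: ``+`` toward higher coordinates, ``-`` toward lower.
    """

    chrom: str
    pos: int
    orientation: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("breakpoint position must be >= 1")
        if self.orientation not in ("+", "-"):
            raise ValueError(f"bad orientation {self.orientation!r}")


@dataclass
class SVEvent:
    """Breakpoint pair with flanking-bin copy number annotation.

    ``c1_up``/``c1_down`` are the copy numbers of the 10 kb bins
    immediately upstream/downstream of breakpoint 1 (likewise ``c2_*``);
    ``c_mean`` is the mean copy number of the bins strictly between
    intra-chromosomal breakpoints. Any of these may be ``None`` when the
    breakpoint falls in an unbinned gap.
    """

    bp1: SVBreakpoint
    bp2: SVBreakpoint
    sv_type: Optional[str] = None
    c1_up: Optional[float] = None
    c1_down: Optional[float] = None
    c2_up: Optional[float] = None
    c2_down: Optional[float] = None
    c_mean: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sv_type is not None and self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")

    @property
    def intrachromosomal(self) -> bool:
        return self.bp1.chrom == self.bp2.chrom

    @property
    def span(self) -> Optional[int]:
        """Distance between breakpoints; undefined across chromosomes."""
        if not self.intrachromosomal:
            return None
        return abs(self.bp2.pos - self.bp1.pos)


@dataclass(frozen=True)
class VariantCall:
    """Filtered small-variant call with the annotations the inclusion
    rules operate on (supporting caller count, ClinVar significance,
    functional class, tumor read counts)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str  # snv | indel
    caller_count: int = 0
    clnsig: str = "."
    func: str = "."
    alt_reads: int = 0
    ref_reads: int = 0
    gene: str = "."
    channel: Optional[int] = None  # 96-channel trinucleotide index for SNVs

    def __post_init__(self) -> None:
        if self.variant_class not in ("snv", "indel"):
            raise ValueError(f"bad variant_class {self.variant_class!r}")

    @property
    def vaf(self) -> float:
        depth = self.alt_reads + self.ref_reads
        return self.alt_reads / depth if depth else 0.0


@dataclass(frozen=True)
class GenomicInterval:
    """Named interval: gene, oncogene, TSG, tiling window, or arm."""

    chrom: str
    start: int
    end: int
    name: str
    role: str = "gene"
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval {self.name}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def overlap(self, chrom: str, start: int, end: int) -> int:
        if chrom != self.chrom:
            return 0
        return max(0, min(self.end, end) - max(self.start, start) + 1)


@dataclass(frozen=True)
class TandemDuplication:
    """Simple tandem duplication called from copy-number segments: a
    copy-gain segment flanked on both sides by lower-copy segments."""

    chrom: str
    start: int
    end: int
    segment_cn: int
    left_flank_cn: int
    right_flank_cn: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class TumorProfile:
    """One sample's somatic landscape: segments + SVs + small variants."""

    sample_id: str
    patient_id: str
    platform: str  # WES | WGS
    purity: float
    ploidy: float
    segments: list = field(default_factory=list)
    svs: list = field(default_factory=list)
    variants: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.platform not in ("WES", "WGS"):
            raise ValueError(f"platform must be WES or WGS, got {self.platform!r}")
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must be in [0, 1]")

    @property
    def eligible(self) -> bool:
        """Analysis eligibility: at least 20% tumor cellularity."""
        return self.purity >= 0.2


def sort_segments(segments):
    """Sort segments by (chrom, start) and verify per-chromosome
    non-overlap; raises ValueError on overlapping input."""
    out = sorted(segments, key=lambda s: (s.chrom, s.start))
    for a, b in zip(out, out[1:]):
        if a.chrom == b.chrom and b.start <= a.end:
            raise ValueError(
                f"overlapping segments on {a.chrom}: "
                f"{a.start}-{a.end} and {b.start}-{b.end}"
            )
    return out


def merge_intervals(intervals):
    """Merge possibly-overlapping (start, end) 1-based inclusive tuples
    and return the merged list plus total covered length."""
    if not intervals:
        return [], 0
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    total = sum(e - s + 1 for s, e in merged)
    return [tuple(m) for m in merged], total


__all__ += ["sort_segments", "merge_intervals", "replace"]
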
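"""Gene-level allelic-status calling (BAL / MAL / Intact).

Variant inclusion rules: SNVs need >= 2 supporting callers, a ClinVar
label other than benign/likely_benign, and an exonic or splicing
functional class; indels additionally need alt reads >= 5, ref reads
>= 10, and VAF > 0.1 (strict).

Copy-number annotation: segments with cellular fraction < 0.8 are
excluded unless copy-neutral or total copy > 4; the gene takes the
copy number and LOH flag of the largest-overlap surviving segment.
Normalised copy number (total / rounded ploidy, halved denominator on
X) is categorised as amplification (>= 2.5), gain ([1.5, 2.5)),
homozygous deletion (raw total 0), deletion with LOH ((0, 1) + LOH),
copy-neutral LOH (= 1 + LOH), else neutral.

Allelic status: biallelic loss (BAL) is a homozygous deletion or >= 2
qualifying events; monoallelic loss (MAL) exactly 1; Intact 0. Events
counted: each retained mutation in the gene, one for a
hemizygous-deletion/copy-neutral LOH, and (by default) one for an SV
transecting the gene body.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import CopyNumberSegment, GenomicInterval, SVEvent, VariantCall
from .sv_typing import is_translocation_like

BENIGN_LABELS = frozenset({"benign", "likely_benign"})
FUNC_CLASSES = frozenset({"exonic", "splicing"})
CF_FLOOR = 0.8
CN_HIGH_KEEP = 4  # segments with total_cn > 4 kept regardless of cellular fraction
AMPLIFICATION_BOUND = 2.5  # inclusive
GAIN_BOUND = 1.5  # inclusive
FLANK_SIZE = 1_000_000  # bp on each side of the gene body

CN_LOSS_CATEGORIES = frozenset({"deletion_LOH", "copy_neutral_LOH"})


@dataclass
class GeneAllelicStatus:
    gene: str
    cn_category: Optional[str]
    normalized_cn: Optional[float]
    loh: bool
    sv_status: str  # transect | flank | none
    n_mutations: int
    n_events: int
    status: str  # BAL | MAL | Intact
    reason: str = ""


def filter_snvs(calls: Iterable[VariantCall]) -> list[VariantCall]:
    """Inclusion rules for SNVs; calls with missing annotations are
    excluded conservatively (with a warning)."""
    out = []
    for v in calls:
        if v.variant_class != "snv":
            continue
        if v.clnsig in (".", "") or v.func in (".", ""):
            warnings.warn(f"SNV {v.chrom}:{v.pos} missing annotations; excluded")
            continue
        if v.caller_count >= 2 and v.clnsig.lower() not in BENIGN_LABELS \
                and v.func.lower() in FUNC_CLASSES:
            out.append(v)
    return out


def filter_indels(calls: Iterable[VariantCall]) -> list[VariantCall]:
    """Inclusion rules for indels (read-support thresholds on top of the
    annotation rules; VAF strictly > 0.1)."""
    out = []
    for v in calls:
        if v.variant_class != "indel":
            continue
        if v.clnsig.lower() in BENIGN_LABELS or v.func.lower() not in FUNC_CLASSES:
            continue
        if v.alt_reads >= 5 and v.ref_reads >= 10 and v.vaf > 0.1:
            out.append(v)
    return out


def filter_variants(calls: Iterable[VariantCall]) -> list[VariantCall]:
    calls = list(calls)
    return filter_snvs(calls) + filter_indels(calls)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def annotate_gene_cn(
    gene: GenomicInterval,
    segments: Iterable[CopyNumberSegment],
    ploidy: float,
    sex_chrom: bool = False,
    cf_floor: float = CF_FLOOR,
):
    """(cn_category, normalized_cn, loh) for the gene, or (None, None,
    False) when no surviving segment overlaps it."""
    denom = _round_half_up(ploidy)
    if denom <= 0:
        raise ValueError("ploidy must round to a positive integer")
    if sex_chrom:
        denom = denom / 2.0

    best = None
    best_ov = 0
    for seg in segments:
        ov = gene.overlap(seg.chrom, seg.start, seg.end)
        if ov == 0:
            continue
        copy_neutral = seg.total_cn == _round_half_up(ploidy)
        if seg.cellular_fraction < cf_floor and not copy_neutral \
                and not seg.total_cn > CN_HIGH_KEEP:
            continue
        if ov > best_ov:
            best, best_ov = seg, ov
    if best is None:
        return None, None, False

    norm = best.total_cn / denom
    loh = best.minor_cn == 0
    if best.total_cn == 0:
        category = "homozygous_deletion"
    elif norm >= AMPLIFICATION_BOUND:
        category = "amplification"
    elif norm >= GAIN_BOUND:
        category = "gain"
    elif 0 < norm < 1 and loh:
        category = "deletion_LOH"
    elif math.isclose(norm, 1.0) and loh:
        category = "copy_neutral_LOH"
    else:
        category = "neutral"
    return category, norm, loh


def _toward_gene(bp, gene: GenomicInterval) -> bool:
    """Is a flank breakpoint oriented toward the gene body? The joined
    fragment extends in the breakpoint's orientation direction."""
    if bp.pos < gene.start:
        return bp.orientation == "+"
    if bp.pos > gene.end:
        return bp.orientation == "-"
    return True


def annotate_gene_sv(
    gene: GenomicInterval,
    svs: Iterable[SVEvent],
    flank: int = FLANK_SIZE,
) -> str:
    """'transect' if any breakpoint falls in the gene body; else 'flank'
    when a short intra-chromosomal TD/deletion/inversion breakpoint lies
    in a 1 Mb flank, or a translocation-like event has a flank
    breakpoint oriented toward the gene; else 'none'."""
    left = GenomicInterval(gene.chrom, max(1, gene.start - flank), gene.start - 1,
                           f"{gene.name}_5p", role="window") if gene.start > 1 else None
    right = GenomicInterval(gene.chrom, gene.end + 1, gene.end + flank,
                            f"{gene.name}_3p", role="window")

    def in_flank(bp) -> bool:
        return (left is not None and left.contains(bp.chrom, bp.pos)) or \
            right.contains(bp.chrom, bp.pos)

    flank_hit = False
    for sv in svs:
        for bp in (sv.bp1, sv.bp2):
            if gene.contains(bp.chrom, bp.pos):
                return "transect"
        if flank_hit:
            continue
        if is_translocation_like(sv):
            for bp in (sv.bp1, sv.bp2):
                if in_flank(bp) and _toward_gene(bp, gene):
                    flank_hit = True
        elif sv.intrachromosomal and sv.sv_type in (
            "tandem_duplication", "deletion", "inversion"
        ):
            if in_flank(sv.bp1) or in_flank(sv.bp2):
                flank_hit = True
    return "flank" if flank_hit else "none"


def call_allelic_status(
    gene: GenomicInterval,
    filtered_variants: Iterable[VariantCall],
    cn_annotation: tuple,
    sv_status: str,
    count_sv_transect: bool = True,
) -> GeneAllelicStatus:
    """Integrate mutations + copy number + SVs into a BAL/MAL/Intact
    call. ``cn_annotation`` is the :func:`annotate_gene_cn` triple;
    ``filtered_variants`` must already have passed the inclusion rules.
    """
    category, norm, loh = cn_annotation
    muts = [
        v for v in filtered_variants
        if v.gene == gene.name or gene.contains(v.chrom, v.pos)
    ]
    n_events = len(muts)
    reasons = [f"{len(muts)} mutation(s)"] if muts else []
    if category in CN_LOSS_CATEGORIES:
        n_events += 1
        reasons.append(category)
    if count_sv_transect and sv_status == "transect":
        n_events += 1
        reasons.append("sv_transect")

    if category == "homozygous_deletion":
        status, reason = "BAL", "homozygous_deletion"
    elif n_events >= 2:
        status, reason = "BAL", "+".join(reasons)
    elif n_events == 1:
        status, reason = "MAL", reasons[0]
    else:
        status, reason = "Intact", ""
    return GeneAllelicStatus(
        gene=gene.name,
        cn_category=category,
        normalized_cn=norm,
        loh=loh,
        sv_status=sv_status,
        n_mutations=len(muts),
        n_events=n_events,
        status=status,
        reason=reason,
    )


def gene_status_table(statuses: Iterable[GeneAllelicStatus]) -> str:
    """TSV rendering of per-gene statuses."""
    lines = ["gene\tcn_category\tnormalized_cn\tloh\tsv_status\tn_events\tstatus"]
    for s in statuses:
        lines.append(
            f"{s.gene}\t{s.cn_category}\t{s.normalized_cn}\t{int(s.loh)}\t"
            f"{s.sv_status}\t{s.n_events}\t{s.status}"
        )
    return "\n".join(lines) + "\n"
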
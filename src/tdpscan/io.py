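"""Readers/writers for the text formats the pipeline consumes.

Dialects
--------
* SEG TSV: ``sample chrom start end total_cn minor_cn cellular_fraction``,
  coordinates 1-based inclusive.
* BEDPE: standard 10 columns, 0-based half-open; each breakend is a
  single base, strand columns carry the junction orientations, the name
  field carries the SV type (``.`` when untyped).
* VCF 4.2 with INFO keys ``VC`` (snv|indel), ``CALLERS``, ``CLNSIG``,
  ``FUNC``, ``GENE``, ``TNC`` (96-channel index) and per-sample ``AD``.
* BED (4+ columns) for genes/windows/arms; column 5 may carry the role.
* Signature matrix TSV: rows = 96 trinucleotide channels, columns =
  signature names, each column summing to 1.

Chromosome names are normalised to a single style on read (``chr``
prefix stripped or added via ``chrom_style``).
"""
from __future__ import annotations

import os
from typing import Iterable, Optional

import pandas as pd
import pysam

from .model import (
    CopyNumberSegment,
    GenomicInterval,
    SVBreakpoint,
    SVEvent,
    TumorProfile,
    VariantCall,
)

SEG_COLUMNS = ["sample", "chrom", "start", "end", "total_cn", "minor_cn", "cellular_fraction"]
BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2",
]

#: chromosomes flagged as sex chromosomes (excluded from LOH scoring by default)
SEX_CHROMS = frozenset({"X", "chrX", "Y", "chrY"})


def normalize_chrom(chrom: str, style: Optional[str] = None) -> str:
    """Normalise chromosome naming. ``style='chr'`` adds the prefix,
    ``style='plain'`` strips it, ``None`` leaves names untouched."""
    if style is None:
        return chrom
    bare = chrom[3:] if chrom.startswith("chr") else chrom
    return f"chr{bare}" if style == "chr" else bare


def _parse_error(path, lineno: int, msg: str) -> ValueError:
    return ValueError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------------
# SEG


def read_segments(path, chrom_style: Optional[str] = None):
    """Read a SEG TSV into ``{sample_id: [CopyNumberSegment, ...]}``."""
    out: dict[str, list] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != SEG_COLUMNS:
            raise ValueError(f"{path}: expected columns {SEG_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(SEG_COLUMNS):
                raise _parse_error(path, lineno, f"expected {len(SEG_COLUMNS)} columns")
            sample, chrom, start, end, total_cn, minor_cn, cf = fields
            start, end = int(start), int(end)
            if end < start:
                raise _parse_error(path, lineno, f"end {end} < start {start}")
            seg = CopyNumberSegment(
                chrom=normalize_chrom(chrom, chrom_style),
                start=start,
                end=end,
                total_cn=int(total_cn),
                minor_cn=int(minor_cn),
                cellular_fraction=float(cf),
            )
            out.setdefault(sample, []).append(seg)
    return out


def write_segments(path, segments_by_sample: dict) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SEG_COLUMNS) + "\n")
        for sample in segments_by_sample:
            for s in segments_by_sample[sample]:
                fh.write(
                    f"{sample}\t{s.chrom}\t{s.start}\t{s.end}\t"
                    f"{s.total_cn}\t{s.minor_cn}\t{s.cellular_fraction!r}\n"
                )


# ---------------------------------------------------------------------------
# BEDPE


def read_svs(path, chrom_style: Optional[str] = None):
    """Read a BEDPE into a list of :class:`SVEvent` (coordinates
    converted 0-based half-open -> 1-based inclusive)."""
    events = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 10:
                raise _parse_error(path, lineno, "expected >= 10 BEDPE columns")
            c1, s1, e1, c2, s2, e2, name, _score, o1, o2 = fields[:10]
            s1, e1, s2, e2 = int(s1), int(e1), int(s2), int(e2)
            if e1 < s1 or e2 < s2:
                raise _parse_error(path, lineno, "coordinate inversion")
            sv_type = None if name in (".", "") else name
            events.append(
                SVEvent(
                    bp1=SVBreakpoint(normalize_chrom(c1, chrom_style), s1 + 1, o1),
                    bp2=SVBreakpoint(normalize_chrom(c2, chrom_style), s2 + 1, o2),
                    sv_type=sv_type,
                )
            )
    return events


def write_svs(path, events: Iterable[SVEvent]) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(BEDPE_COLUMNS) + "\n")
        for ev in events:
            name = ev.sv_type or "."
            fh.write(
                f"{ev.bp1.chrom}\t{ev.bp1.pos - 1}\t{ev.bp1.pos}\t"
                f"{ev.bp2.chrom}\t{ev.bp2.pos - 1}\t{ev.bp2.pos}\t"
                f"{name}\t.\t{ev.bp1.orientation}\t{ev.bp2.orientation}\n"
            )


# ---------------------------------------------------------------------------
# VCF


_VCF_INFO_HEADERS = [
    '##INFO=<ID=VC,Number=1,Type=String,Description="Variant class (snv|indel)">',
    '##INFO=<ID=CALLERS,Number=1,Type=Integer,Description="Number of supporting callers">',
    '##INFO=<ID=CLNSIG,Number=1,Type=String,Description="ClinVar significance label">',
    '##INFO=<ID=FUNC,Number=1,Type=String,Description="Functional class">',
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=TNC,Number=1,Type=Integer,Description="Trinucleotide channel index (0-95)">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
]


def write_variants(path, variants: Iterable[VariantCall], sample_id: str,
                   contigs: Optional[Iterable[tuple]] = None) -> None:
    """Write variants as uncompressed VCF 4.2. ``contigs`` is an iterable
    of (name, length) for the header; inferred from variants if omitted."""
    variants = list(variants)
    if contigs is None:
        seen: dict[str, int] = {}
        for v in variants:
            seen[v.chrom] = max(seen.get(v.chrom, 0), v.pos + 1000)
        contigs = sorted(seen.items())
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("\n".join(_VCF_INFO_HEADERS) + "\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + sample_id + "\n"
        )
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            info = (
                f"VC={v.variant_class};CALLERS={v.caller_count};"
                f"CLNSIG={v.clnsig};FUNC={v.func};GENE={v.gene}"
            )
            if v.channel is not None:
                info += f";TNC={v.channel}"
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\t"
                f"AD\t{v.ref_reads},{v.alt_reads}\n"
            )


def read_variants(path, chrom_style: Optional[str] = None):
    """Read a VCF written by :func:`write_variants` (or any VCF carrying
    the same INFO keys) into a list of :class:`VariantCall`."""
    out = []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        for rec in vcf:
            info = rec.info
            ad = None
            for sample in rec.samples.values():
                ad = sample.get("AD")
                break
            ref_reads, alt_reads = (int(ad[0]), int(ad[1])) if ad else (0, 0)
            out.append(
                VariantCall(
                    chrom=normalize_chrom(rec.chrom, chrom_style),
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0] if rec.alts else ".",
                    variant_class=str(info.get("VC", "snv")),
                    caller_count=int(info.get("CALLERS", 0)),
                    clnsig=str(info.get("CLNSIG", ".")),
                    func=str(info.get("FUNC", ".")),
                    alt_reads=alt_reads,
                    ref_reads=ref_reads,
                    gene=str(info.get("GENE", ".")),
                    channel=int(info["TNC"]) if "TNC" in info else None,
                )
            )
    return out


# ---------------------------------------------------------------------------
# BED intervals


def read_intervals(path, role: Optional[str] = None,
                   chrom_style: Optional[str] = None):
    """Read a BED (0-based half-open) into :class:`GenomicInterval`
    records. Column 5, when present and non-numeric, carries the role;
    a ``role`` argument overrides it."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise _parse_error(path, lineno, "expected >= 4 BED columns")
            chrom, start, end, name = fields[:4]
            start, end = int(start), int(end)
            if end <= start:
                raise _parse_error(path, lineno, "empty or inverted interval")
            row_role = role
            if row_role is None:
                row_role = fields[4] if len(fields) > 4 and fields[4] else "gene"
            strand = fields[5] if len(fields) > 5 else "+"
            out.append(
                GenomicInterval(
                    chrom=normalize_chrom(chrom, chrom_style),
                    start=start + 1,
                    end=end,
                    name=name,
                    role=row_role,
                    strand=strand,
                )
            )
    return out


def write_intervals(path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.name}\t{iv.role}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# signature matrix


def read_signature_matrix(path) -> pd.DataFrame:
    """96-channel signature reference: rows = channels, columns =
    signatures, each column summing to ~1."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    if mat.shape[0] != 96:
        raise ValueError(f"{path}: expected 96 channel rows, got {mat.shape[0]}")
    colsum = mat.sum(axis=0)
    if not ((colsum - 1.0).abs() < 1e-6).all():
        raise ValueError(f"{path}: signature columns must each sum to 1")
    return mat


def write_signature_matrix(path, mat: pd.DataFrame) -> None:
    mat.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# cohort metadata / profiles


def write_metadata(path, profiles: Iterable[TumorProfile]) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpatient_id\tplatform\tpurity\tploidy\n")
        for p in profiles:
            fh.write(
                f"{p.sample_id}\t{p.patient_id}\t{p.platform}\t"
                f"{p.purity!r}\t{p.ploidy!r}\n"
            )


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})
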
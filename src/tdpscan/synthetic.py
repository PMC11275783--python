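"""Synthetic tumor-genome cohorts with known truth.

The generator emulates the statistical structure of a metastatic
prostate-cancer cohort at the level this pipeline consumes: baseline
allele-specific copy-number segments per chromosome arm, simple tandem
duplications (one extra copy, lower-copy flanks, matching tail-to-head
breakpoints), genome-wide and arm-level LOH, 96-channel mutation
catalogs drawn from signature mixtures, and per-gene event
configurations with known allelic-status truth.

TD placement modes
------------------
``random``    uniform over arms (nearest-neighbor index ~ 1);
``dispersed`` jittered regular spacing (NNI well above 1, the regime of
              genuine tandem-duplicator genomes);
``clustered`` confined to a few 2 Mb windows (NNI << 1).

TD lengths are log-normal in log10(kb) around configurable mode(s);
the canonical bimodal setting 230 kb / 1.7 Mb reproduces the Group-6
size profile, unimodal ~10 kb the Group-1 profile.

Every simulated TD satisfies the TD-calling criteria by construction,
and placement keeps a 1.1 Mb guard zone around configured genes so
per-gene truth is not perturbed by background events.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as tio
from .model import (
    CopyNumberSegment,
    GenomicInterval,
    SVBreakpoint,
    SVEvent,
    TumorProfile,
    VariantCall,
)
from .tdp import _GROUP_BY_BINS, _bin_of

MAX_PLACEMENT_RETRIES = 1000
TD_GUARD = 2_000  # bp clearance between TDs and from arm edges
GENE_GUARD = 1_100_000  # bp guard zone around genes (flank size + margin)
CLUSTER_WINDOW = 2_000_000  # bp window width for clustered placement

# 96-channel labels in COSMIC order: C>A, C>G, C>T, T>A, T>C, T>G x 16 contexts
_SUBS = [("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G")]
_BASES = "ACGT"
CHANNELS = [
    f"{five}[{ref}>{alt}]{three}"
    for ref, alt in _SUBS
    for five in _BASES
    for three in _BASES
]


def channel_ref_alt(channel: int) -> tuple:
    """Central ref/alt bases of a 96-channel index."""
    ref, alt = _SUBS[channel // 16]
    return ref, alt


def make_signature_matrix(
    names: Sequence[str] = ("SBS1", "SBS3", "SBS5", "SBS8"),
    seed: int = 20260901,
    sparsity: float = 0.6,
) -> pd.DataFrame:
    """Deterministic synthetic 96-channel signature reference.

    These are synthetic stand-ins for COSMIC single-base-substitution
    profiles: each column is a sparse-ish random probability vector
    (columns sum to 1), distinct enough for non-negative least-squares
    refitting to separate them.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    for name in names:
        raw = rng.gamma(0.5, 1.0, size=96)
        mask = rng.random(96) < sparsity
        raw[mask] *= 0.02
        cols[name] = raw / raw.sum()
    return pd.DataFrame(cols, index=CHANNELS)


# ---------------------------------------------------------------------------
# configuration


def default_genome_layout():
    """(chrom, length bp, centromere bp) for a compact 8-chromosome
    synthetic genome (~1.36 Gb)."""
    lengths = [240, 220, 200, 180, 160, 140, 120, 100]
    return tuple(
        (f"chr{i + 1}", L * 1_000_000, int(L * 1_000_000 * 0.4))
        for i, L in enumerate(lengths)
    )


def arms_from_layout(layout) -> list[GenomicInterval]:
    arms = []
    for chrom, length, cen in layout:
        arms.append(GenomicInterval(chrom, 1, cen, f"{chrom}p", role="arm"))
        arms.append(GenomicInterval(chrom, cen + 1, length, f"{chrom}q", role="arm"))
    return arms


def default_genes() -> tuple:
    """Six synthetic genes (~100 kb each) spread over the genome."""
    spots = [
        ("GENE_A", "chr5", 30_000_000),
        ("GENE_B", "chr5", 90_000_000),
        ("GENE_C", "chr6", 40_000_000),
        ("GENE_D", "chr7", 20_000_000),
        ("GENE_E", "chr7", 80_000_000),
        ("GENE_F", "chr8", 50_000_000),
    ]
    return tuple(
        GenomicInterval(chrom, start, start + 99_999, name, role="gene")
        for name, chrom, start in spots
    )


@dataclass(frozen=True)
class SampleSpec:
    """Per-sample simulation parameters."""

    tdp_status: str = "negative"  # intended truth: positive | negative
    n_tds: int = 0
    length_modes_bp: tuple = (230_000, 1_700_000)
    log10_sd: float = 0.25
    placement: str = "dispersed"  # dispersed | random | clustered
    n_clusters: int = 3
    loh_fraction: float = 0.0
    arm_loh_events: tuple = ()  # ((arm_name, fraction), ...)
    n_snvs: int = 0
    exposures: tuple = ()  # ((signature, weight), ...) summing to 1
    gene_events: tuple = ()  # ((gene_name, (event_kind, ...)), ...)
    purity: float = 0.61
    ploidy: float = 2.0
    platform: str = "WGS"

    def validate(self, genes: Sequence[GenomicInterval]) -> None:
        if self.tdp_status not in ("positive", "negative"):
            raise ValueError(f"bad tdp_status {self.tdp_status!r}")
        if self.n_tds < 0:
            raise ValueError("n_tds must be >= 0")
        if not 0.0 <= self.loh_fraction <= 1.0:
            raise ValueError("loh_fraction must be in [0, 1]")
        if self.placement not in ("dispersed", "random", "clustered"):
            raise ValueError(f"bad placement {self.placement!r}")
        if any(m <= 0 for m in self.length_modes_bp):
            raise ValueError("length modes must be positive")
        if self.exposures:
            total = sum(w for _, w in self.exposures)
            if abs(total - 1.0) > 1e-9:
                raise ValueError("exposure weights must sum to 1")
        gene_names = {g.name for g in genes}
        for name, _events in self.gene_events:
            if name not in gene_names:
                raise ValueError(f"gene_events references unknown gene {name!r}")


@dataclass(frozen=True)
class SimConfig:
    samples: tuple  # of SampleSpec
    genome_layout: tuple = field(default_factory=default_genome_layout)
    genes: tuple = field(default_factory=default_genes)
    seed: int = 0

    def __post_init__(self):
        for spec in self.samples:
            spec.validate(self.genes)
        for chrom, length, cen in self.genome_layout:
            if length <= 0 or not 0 < cen < length:
                raise ValueError(f"bad layout entry for {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def chrom_lengths(self) -> dict:
        return {c: L for c, L, _ in self.genome_layout}

    @property
    def genome_length(self) -> int:
        return sum(L for _, L, _ in self.genome_layout)


@dataclass
class TruthRecord:
    sample_id: str
    tdp_status: str
    size_group: Optional[int]
    loh_fraction: float  # realized fraction of the genome
    exposures: dict
    gene_status: dict  # gene -> BAL | MAL | Intact
    td_intervals: list = field(default_factory=list)

    def __post_init__(self):
        if self.size_group is not None and self.tdp_status != "positive":
            raise ValueError("size_group only meaningful for TDP-positive truth")


class PlacementError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# low-level draws


def simulate_td_lengths(n: int, modes_bp: Sequence[float], log10_sd: float, rng) -> np.ndarray:
    """Log-normal TD lengths (bp) in log10(kb) space around the given
    mode(s), equal mixture weights, clipped to (1.5 kb, 9.5 Mb) so every
    draw passes the span and 10 Mb criteria."""
    modes = np.asarray(modes_bp, dtype=float)
    pick = rng.integers(0, len(modes), size=n)
    draws = rng.normal(np.log10(modes[pick] / 1000.0), log10_sd)
    return np.clip(10.0 ** draws * 1000.0, 1_500, 9_500_000)


def simulate_mutation_catalog(
    exposures, n: int, signature_matrix: pd.DataFrame, rng
) -> np.ndarray:
    """Multinomial 96-channel catalog from matrix x exposures, total n."""
    if n <= 0:
        raise ValueError("catalog size n must be positive")
    e = np.asarray(exposures, dtype=float)
    if e.shape[0] != signature_matrix.shape[1]:
        raise ValueError("exposure vector must match signature columns")
    if abs(e.sum() - 1.0) > 1e-9:
        raise ValueError("exposures must sum to 1")
    p = signature_matrix.to_numpy(dtype=float) @ e
    p = p / p.sum()
    return rng.multinomial(n, p)


# ---------------------------------------------------------------------------
# placement


def _usable_regions(config: SimConfig) -> list:
    """(chrom, lo, hi) arm intervals shrunk by the TD guard and with
    gene neighborhoods removed."""
    forbidden: dict[str, list] = {}
    for g in config.genes:
        forbidden.setdefault(g.chrom, []).append(
            (max(1, g.start - GENE_GUARD), g.end + GENE_GUARD)
        )
    regions = []
    for arm in arms_from_layout(config.genome_layout):
        lo, hi = arm.start + TD_GUARD, arm.end - TD_GUARD
        pieces = [(lo, hi)]
        for f_lo, f_hi in forbidden.get(arm.chrom, ()):
            nxt = []
            for p_lo, p_hi in pieces:
                if f_hi < p_lo or f_lo > p_hi:
                    nxt.append((p_lo, p_hi))
                    continue
                if f_lo > p_lo:
                    nxt.append((p_lo, f_lo - 1))
                if f_hi < p_hi:
                    nxt.append((f_hi + 1, p_hi))
            pieces = nxt
        for p_lo, p_hi in pieces:
            if p_hi - p_lo > 4 * TD_GUARD:
                regions.append((arm.chrom, p_lo, p_hi))
    return regions


def _fits(chrom, start, end, placed, regions) -> bool:
    inside = any(
        chrom == c and start >= lo and end <= hi for c, lo, hi in regions
    )
    if not inside:
        return False
    for c, s, e in placed:
        if c == chrom and start <= e + TD_GUARD and end >= s - TD_GUARD:
            return False
    return True


def _allocate(counts_weights, n, rng) -> list:
    """Largest-remainder allocation of n items over weights."""
    w = np.asarray(counts_weights, dtype=float)
    raw = n * w / w.sum()
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    if rem > 0:
        order = np.argsort(-(raw - base))
        base[order[:rem]] += 1
    return list(base)


def place_tds(config: SimConfig, spec: SampleSpec, rng) -> list:
    """Non-overlapping (chrom, start, end) TD intervals under the
    requested placement mode; raises PlacementError after bounded
    retries."""
    if spec.n_tds == 0:
        return []
    regions = _usable_regions(config)
    lengths = simulate_td_lengths(spec.n_tds, spec.length_modes_bp, spec.log10_sd, rng)
    weights = [hi - lo for _, lo, hi in regions]
    placed: list = []

    if spec.placement == "dispersed":
        alloc = _allocate(weights, spec.n_tds, rng)
        li = 0
        for (chrom, lo, hi), m in zip(regions, alloc):
            if m == 0:
                continue
            slot = (hi - lo) / m
            for i in range(m):
                length = lengths[li]
                li += 1
                ok = False
                for _ in range(MAX_PLACEMENT_RETRIES):
                    mid = lo + (i + 0.5) * slot + rng.uniform(-0.25, 0.25) * slot
                    start = int(mid - length / 2)
                    end = start + int(length) - 1
                    if _fits(chrom, start, end, placed, regions):
                        placed.append((chrom, start, end))
                        ok = True
                        break
                if not ok:
                    raise PlacementError(f"cannot place dispersed TD on {chrom}")
    elif spec.placement == "random":
        for length in lengths:
            ok = False
            for _ in range(MAX_PLACEMENT_RETRIES):
                ri = rng.choice(len(regions), p=np.asarray(weights) / sum(weights))
                chrom, lo, hi = regions[ri]
                mid = rng.uniform(lo, hi)
                start = int(mid - length / 2)
                end = start + int(length) - 1
                if _fits(chrom, start, end, placed, regions):
                    placed.append((chrom, start, end))
                    ok = True
                    break
            if not ok:
                raise PlacementError(f"cannot place random TD (len {int(length)})")
    else:  # clustered
        centers = []
        for _ in range(spec.n_clusters):
            ri = rng.choice(len(regions), p=np.asarray(weights) / sum(weights))
            chrom, lo, hi = regions[ri]
            centers.append((chrom, rng.uniform(lo, hi), lo, hi))
        for length in lengths:
            ok = False
            for _ in range(MAX_PLACEMENT_RETRIES):
                chrom, center, lo, hi = centers[rng.integers(0, len(centers))]
                mid = center + rng.uniform(-0.5, 0.5) * CLUSTER_WINDOW
                start = int(mid - length / 2)
                end = start + int(length) - 1
                if _fits(chrom, start, end, placed, regions):
                    placed.append((chrom, start, end))
                    ok = True
                    break
            if not ok:
                raise PlacementError(
                    f"cannot place clustered TD (len {int(length)}) near {chrom}"
                )
    placed.sort()
    return placed


# ---------------------------------------------------------------------------
# segment assembly


def _overlay(segments, chrom, start, end, total=None, minor=None, cf=None):
    """Split segments against [start, end] on chrom and replace fields
    on the intersected pieces."""
    out = []
    for seg in segments:
        if seg.chrom != chrom or seg.end < start or seg.start > end:
            out.append(seg)
            continue
        if seg.start < start:
            out.append(replace(seg, end=start - 1))
        mid_lo, mid_hi = max(seg.start, start), min(seg.end, end)
        new_total = seg.total_cn if total is None else total
        new_minor = seg.minor_cn if minor is None else minor
        new_minor = min(new_minor, new_total)
        out.append(
            replace(
                seg,
                start=mid_lo,
                end=mid_hi,
                total_cn=new_total,
                minor_cn=new_minor,
                cellular_fraction=seg.cellular_fraction if cf is None else cf,
            )
        )
        if seg.end > end:
            out.append(replace(seg, start=end + 1))
    out.sort(key=lambda s: (s.chrom, s.start))
    return out


def _clip_against(pieces, blockers):
    """Remove blocker overlaps from (start, end) pieces on one chrom."""
    for b_lo, b_hi in blockers:
        nxt = []
        for lo, hi in pieces:
            if b_hi < lo or b_lo > hi:
                nxt.append((lo, hi))
                continue
            if b_lo > lo:
                nxt.append((lo, b_lo - 1))
            if b_hi < hi:
                nxt.append((b_hi + 1, hi))
        pieces = nxt
    return pieces


def simulate_tumor(config: SimConfig, sample_index: int):
    """Build one (TumorProfile, TruthRecord) pair; fully deterministic
    given config.seed and sample_index."""
    if not 0 <= sample_index < config.n_samples:
        raise IndexError(f"sample_index {sample_index} out of range")
    spec = config.samples[sample_index]
    rng = np.random.default_rng([config.seed, sample_index])
    sample_id = f"S{sample_index:03d}"
    base_cn = int(np.floor(spec.ploidy + 0.5))
    base_minor = base_cn // 2

    # baseline: one segment per arm
    segments = [
        CopyNumberSegment(a.chrom, a.start, a.end, base_cn, base_minor, 1.0)
        for a in arms_from_layout(config.genome_layout)
    ]

    # tandem duplications: +1 copy, matching tail-to-head breakpoints
    td_intervals = place_tds(config, spec, rng)
    svs = []
    for chrom, start, end in td_intervals:
        segments = _overlay(segments, chrom, start, end, total=base_cn + 1,
                            minor=base_minor)
        svs.append(
            SVEvent(
                bp1=SVBreakpoint(chrom, start, "-"),
                bp2=SVBreakpoint(chrom, end, "+"),
                sv_type="tandem_duplication",
            )
        )

    # gene events
    gene_by_name = {g.name: g for g in config.genes}
    gene_truth = {g.name: "Intact" for g in config.genes}
    variants: list = []
    for gene_name, events in spec.gene_events:
        gene = gene_by_name[gene_name]
        n_mut = 0
        cn_loss = False
        hom_del = False
        sv_hit = False
        offset = 0
        for kind in events:
            offset += 7_000
            pos = gene.start + offset
            if kind == "snv":
                channel = int(rng.integers(0, 96))
                ref, alt = channel_ref_alt(channel)
                variants.append(
                    VariantCall(gene.chrom, pos, ref, alt, "snv", caller_count=3,
                                clnsig="pathogenic", func="exonic", alt_reads=30,
                                ref_reads=60, gene=gene_name, channel=channel)
                )
                n_mut += 1
            elif kind == "benign_snv":
                variants.append(
                    VariantCall(gene.chrom, pos, "C", "T", "snv", caller_count=3,
                                clnsig="benign", func="exonic", alt_reads=30,
                                ref_reads=60, gene=gene_name, channel=1)
                )
            elif kind == "indel":
                variants.append(
                    VariantCall(gene.chrom, pos, "CTT", "C", "indel", caller_count=1,
                                clnsig="pathogenic", func="exonic", alt_reads=12,
                                ref_reads=40, gene=gene_name)
                )
                n_mut += 1
            elif kind == "weak_indel":
                variants.append(
                    VariantCall(gene.chrom, pos, "CA", "C", "indel", caller_count=1,
                                clnsig="pathogenic", func="exonic", alt_reads=4,
                                ref_reads=50, gene=gene_name)
                )
            elif kind == "hemizygous_deletion":
                segments = _overlay(segments, gene.chrom, gene.start - 10_000,
                                    gene.end + 10_000, total=max(0, base_cn - 1),
                                    minor=0)
                cn_loss = True
            elif kind == "homozygous_deletion":
                segments = _overlay(segments, gene.chrom, gene.start - 10_000,
                                    gene.end + 10_000, total=0, minor=0)
                hom_del = True
            elif kind == "cn_loh":
                segments = _overlay(segments, gene.chrom, gene.start - 10_000,
                                    gene.end + 10_000, total=base_cn, minor=0)
                cn_loss = True
            elif kind == "sv_transect":
                mid = (gene.start + gene.end) // 2
                svs.append(
                    SVEvent(
                        bp1=SVBreakpoint(gene.chrom, mid, "+"),
                        bp2=SVBreakpoint(gene.chrom, mid + 3_000_000, "-"),
                        sv_type="deletion",
                    )
                )
                sv_hit = True
            else:
                raise ValueError(f"unknown gene event kind {kind!r}")
        n_events = n_mut + (1 if cn_loss else 0) + (1 if sv_hit else 0)
        if hom_del:
            gene_truth[gene_name] = "BAL"
        elif n_events >= 2:
            gene_truth[gene_name] = "BAL"
        elif n_events == 1:
            gene_truth[gene_name] = "MAL"

    # LOH: explicit arm events first, then dispersed fill to the target
    arms = arms_from_layout(config.genome_layout)
    arm_by_name = {a.name: a for a in arms}
    blockers: dict[str, list] = {}
    for chrom, s, e in td_intervals:
        blockers.setdefault(chrom, []).append((s, e))
    for g in config.genes:
        blockers.setdefault(g.chrom, []).append(
            (max(1, g.start - GENE_GUARD), g.end + GENE_GUARD)
        )
    loh_placed: dict[str, list] = {}
    realized = 0

    def apply_loh(chrom, lo, hi):
        nonlocal segments, realized
        pieces = _clip_against([(lo, hi)], blockers.get(chrom, []))
        pieces = _clip_against(pieces, loh_placed.get(chrom, []))
        for p_lo, p_hi in pieces:
            segments = _overlay(segments, chrom, p_lo, p_hi, minor=0)
            loh_placed.setdefault(chrom, []).append((p_lo, p_hi))
            realized += p_hi - p_lo + 1
        return sum(hi - lo + 1 for lo, hi in pieces)

    for arm_name, fraction in spec.arm_loh_events:
        arm = arm_by_name[arm_name]
        span = int(fraction * arm.length)
        if span > 0:
            apply_loh(arm.chrom, arm.start, arm.start + span - 1)

    target = int(spec.loh_fraction * config.genome_length)
    attempts = 0
    while realized < target and attempts < 5 * MAX_PLACEMENT_RETRIES:
        attempts += 1
        arm = arms[rng.integers(0, len(arms))]
        remaining = target - realized
        span = int(min(remaining, rng.uniform(5e6, 3e7)))
        if span <= 0:
            break
        lo = int(rng.uniform(arm.start, max(arm.start, arm.end - span)))
        apply_loh(arm.chrom, lo, min(arm.end, lo + span - 1))

    # background mutation catalog
    exposures_dict = dict(spec.exposures)
    if spec.n_snvs > 0 and exposures_dict:
        sig = make_signature_matrix(tuple(exposures_dict))
        catalog = simulate_mutation_catalog(
            [exposures_dict[c] for c in sig.columns], spec.n_snvs, sig, rng
        )
        chroms = [c for c, _, _ in config.genome_layout]
        lens = np.array([L for _, L, _ in config.genome_layout], dtype=float)
        gene_zones = {
            g.chrom: (g.start - GENE_GUARD, g.end + GENE_GUARD) for g in config.genes
        }
        for channel, count in enumerate(catalog):
            ref, alt = channel_ref_alt(channel)
            for _ in range(int(count)):
                for _ in range(MAX_PLACEMENT_RETRIES):
                    ci = rng.choice(len(chroms), p=lens / lens.sum())
                    pos = int(rng.integers(1, int(lens[ci])))
                    zone = gene_zones.get(chroms[ci])
                    if zone is None or not zone[0] <= pos <= zone[1]:
                        break
                variants.append(
                    VariantCall(chroms[ci], pos, ref, alt, "snv", caller_count=2,
                                clnsig="uncertain_significance", func="exonic",
                                alt_reads=25, ref_reads=50, channel=channel)
                )

    profile = TumorProfile(
        sample_id=sample_id,
        patient_id=f"P{sample_index:03d}",
        platform=spec.platform,
        purity=spec.purity,
        ploidy=spec.ploidy,
        segments=sorted(segments, key=lambda s: (s.chrom, s.start)),
        svs=svs,
        variants=sorted(variants, key=lambda v: (v.chrom, v.pos)),
    )

    if spec.tdp_status == "positive":
        bins = {
            b for b in (_bin_of(np.log10(m / 1000.0)) for m in spec.length_modes_bp)
            if b is not None
        }
        size_group = _GROUP_BY_BINS.get(frozenset(bins))
    else:
        size_group = None
    truth = TruthRecord(
        sample_id=sample_id,
        tdp_status=spec.tdp_status,
        size_group=size_group,
        loh_fraction=realized / config.genome_length,
        exposures=exposures_dict,
        gene_status=gene_truth,
        td_intervals=td_intervals,
    )
    return profile, truth


def simulate_cohort(config: SimConfig):
    profiles, truths = [], []
    for i in range(config.n_samples):
        p, t = simulate_tumor(config, i)
        profiles.append(p)
        truths.append(t)
    return profiles, truths


# ---------------------------------------------------------------------------
# cohort output


def write_cohort(profiles: Iterable[TumorProfile], truths, out_dir,
                 layout=None) -> dict:
    """Write per-sample SEG/BEDPE/VCF plus cohort metadata and truth
    TSVs; returns the file manifest. Round-trips through the
    :mod:`tdpscan.io` readers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profiles = list(profiles)
    manifest = {"metadata": str(out / "metadata.tsv"), "samples": {}}
    tio.write_metadata(out / "metadata.tsv", profiles)
    contigs = [(c, L) for c, L, _ in (layout or default_genome_layout())]
    for p in profiles:
        entry = {
            "seg": str(out / f"{p.sample_id}.seg.tsv"),
            "bedpe": str(out / f"{p.sample_id}.bedpe"),
            "vcf": str(out / f"{p.sample_id}.vcf"),
        }
        tio.write_segments(entry["seg"], {p.sample_id: p.segments})
        tio.write_svs(entry["bedpe"], p.svs)
        tio.write_variants(entry["vcf"], p.variants, p.sample_id, contigs=contigs)
        manifest["samples"][p.sample_id] = entry
    if truths is not None:
        manifest["truth"] = str(out / "truth.tsv")
        with open(manifest["truth"], "w") as fh:
            fh.write("sample_id\ttdp_status\tsize_group\tloh_fraction\t"
                     "exposures\tgene_status\n")
            for t in truths:
                fh.write(
                    f"{t.sample_id}\t{t.tdp_status}\t"
                    f"{t.size_group if t.size_group is not None else 'none'}\t"
                    f"{t.loh_fraction!r}\t{json.dumps(t.exposures)}\t"
                    f"{json.dumps(t.gene_status)}\n"
                )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def read_cohort(out_dir):
    """Re-assemble TumorProfiles from a written cohort directory."""
    out = Path(out_dir)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    meta = tio.read_metadata(manifest["metadata"])
    profiles = []
    for _, row in meta.iterrows():
        sid = row["sample_id"]
        entry = manifest["samples"][sid]
        segs = tio.read_segments(entry["seg"]).get(sid, [])
        profiles.append(
            TumorProfile(
                sample_id=sid,
                patient_id=row["patient_id"],
                platform=row["platform"],
                purity=float(row["purity"]),
                ploidy=float(row["ploidy"]),
                segments=segs,
                svs=tio.read_svs(entry["bedpe"]),
                variants=tio.read_variants(entry["vcf"]),
            )
        )
    return profiles
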
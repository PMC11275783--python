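"""Sample- and cohort-level orchestration.

``run_sample`` takes a parsed :class:`~tdpscan.model.TumorProfile`
through TD calling, TDP classification (with size grouping for
positives), scar metrics, and per-gene allelic status. ``run_cohort``
aggregates eligible samples into the cohort tables (TDP counts, window
and gene enrichment, per-patient TD phylogenies). Samples below 20%
purity are marked ineligible and excluded from cohort statistics.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats, gene_status, phylogeny, scars, sv_typing, td_caller, tdp
from .io import SEX_CHROMS
from .model import GenomicInterval, TumorProfile
from .synthetic import CHANNELS

MIN_PURITY = 0.2


@dataclass
class PipelineConfig:
    """Every analysis threshold, with its default."""

    max_td_length: int = 10_000_000
    breakpoint_tol: int = 10_000
    require_both_ends: bool = True
    nni_threshold_wes: float = 1.0
    nni_threshold_wgs: float = 1.25
    median_length_threshold: int = 100_000
    gmm_max_components: int = 4
    gmm_weight_floor: float = 0.1
    gmm_variance_ceiling: Optional[float] = None
    arm_loh_exclusion: float = 0.75
    min_snvs: int = 50
    hrd_proportion_threshold: float = 0.05
    hrd_signatures: tuple = ("SBS3", "SBS8")
    cf_floor: float = 0.8
    flank_size: int = 1_000_000
    long_span: int = 10_000_000
    count_sv_transect: bool = True
    min_reciprocal_overlap: float = 0.9
    window_size: int = 50_000
    window_alpha: float = 0.001
    gene_alpha: float = 0.01
    min_purity: float = MIN_PURITY
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        if isinstance(cfg.hrd_signatures, list):
            cfg.hrd_signatures = tuple(cfg.hrd_signatures)
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["hrd_signatures"] = list(self.hrd_signatures)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        data = asdict(self)
        data["hrd_signatures"] = list(self.hrd_signatures)
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @property
    def nni_thresholds(self) -> dict:
        return {"WES": self.nni_threshold_wes, "WGS": self.nni_threshold_wgs}


@dataclass
class SampleBundle:
    sample_id: str
    eligible: bool
    tds: list = field(default_factory=list)
    tdp_call: Optional[tdp.TDPCall] = None
    scar_report: Optional[scars.ScarReport] = None
    gene_statuses: list = field(default_factory=list)
    warnings: list = field(default_factory=list)


def catalog_from_variants(variants) -> np.ndarray:
    """96-channel catalog from SNVs carrying a trinucleotide channel
    index (variants without one are skipped)."""
    catalog = np.zeros(len(CHANNELS), dtype=int)
    for v in variants:
        if v.variant_class == "snv" and v.channel is not None:
            catalog[v.channel] += 1
    return catalog


def run_sample(
    profile: TumorProfile,
    config: PipelineConfig,
    genes: Iterable[GenomicInterval],
    arms: Iterable[GenomicInterval],
    chrom_lengths: dict,
    signature_matrix: Optional[pd.DataFrame] = None,
) -> SampleBundle:
    """Per-sample analysis bundle; ineligible samples (purity below the
    floor) get no downstream outputs."""
    bundle = SampleBundle(sample_id=profile.sample_id,
                          eligible=profile.purity >= config.min_purity)
    if not bundle.eligible:
        bundle.warnings.append(
            f"purity {profile.purity} below {config.min_purity}; excluded"
        )
        return bundle
    arms = list(arms)
    genes = list(genes)

    # tandem duplications
    tds = td_caller.call_simple_tds(profile.segments, max_len=config.max_td_length,
                                    arms=arms)
    svs = sv_typing.filter_svs_by_span(profile.svs)
    if profile.platform == "WGS" and svs:
        tds = td_caller.intersect_tds_with_sv(
            tds, svs, tol=config.breakpoint_tol,
            require_both_ends=config.require_both_ends,
        )
    bundle.tds = tds

    # TDP status + size group
    call = tdp.classify_tdp(
        tds, profile.platform, chrom_lengths, sample_id=profile.sample_id,
        nni_thresholds=config.nni_thresholds,
        median_length_threshold=config.median_length_threshold,
    )
    if call.tdp_status == "positive":
        model = tdp.fit_size_group(
            [t.length for t in tds], seed=config.seed,
            max_components=config.gmm_max_components,
            weight_floor=config.gmm_weight_floor,
            variance_ceiling=config.gmm_variance_ceiling,
        )
        call.size_group = model.group
    bundle.tdp_call = call

    # scar metrics
    filtered = gene_status.filter_variants(profile.variants)
    snvs = [v for v in filtered if v.variant_class == "snv"]
    catalog = catalog_from_variants(snvs)
    bundle.scar_report = scars.scar_report(
        profile.sample_id, profile.segments, arms, catalog,
        signature_matrix, n_snvs=len(snvs),
    )

    # gene allelic status
    for gene in genes:
        cn_ann = gene_status.annotate_gene_cn(
            gene, profile.segments, profile.ploidy,
            sex_chrom=gene.chrom in SEX_CHROMS, cf_floor=config.cf_floor,
        )
        sv_status = gene_status.annotate_gene_sv(gene, svs, flank=config.flank_size)
        bundle.gene_statuses.append(
            gene_status.call_allelic_status(
                gene, filtered, cn_ann, sv_status,
                count_sv_transect=config.count_sv_transect,
            )
        )
    return bundle


@dataclass
class CohortReport:
    config_hash: str
    n_samples: int
    n_eligible: int
    bundles: list
    tdp_counts: dict
    status_counts: dict  # gene -> {BAL, MAL, Intact}
    window_enrichment: list = field(default_factory=list)
    trees: dict = field(default_factory=dict)  # patient -> newick
    flagged_for_review: list = field(default_factory=list)  # (patient, gene)

    def summary(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "n_samples": self.n_samples,
            "n_eligible": self.n_eligible,
            "tdp_counts": self.tdp_counts,
            "gene_status_counts": self.status_counts,
            "n_significant_windows": sum(
                1 for r in self.window_enrichment if r.significant
            ),
            "patients_with_trees": sorted(self.trees),
            "flagged_for_review": self.flagged_for_review,
        }


def run_cohort(
    profiles: Iterable[TumorProfile],
    config: PipelineConfig,
    genes: Iterable[GenomicInterval],
    arms: Iterable[GenomicInterval],
    chrom_lengths: dict,
    signature_matrix: Optional[pd.DataFrame] = None,
    windows: Optional[list] = None,
) -> CohortReport:
    profiles = list(profiles)
    if not profiles:
        raise ValueError("empty cohort")
    genes = list(genes)
    arms = list(arms)
    bundles = [
        run_sample(p, config, genes, arms, chrom_lengths, signature_matrix)
        for p in profiles
    ]
    eligible = [b for b in bundles if b.eligible]

    tdp_counts = {"positive": 0, "negative": 0, "unevaluable": 0}
    for b in eligible:
        tdp_counts[b.tdp_call.tdp_status] += 1

    status_counts: dict = {}
    for b in eligible:
        for gs in b.gene_statuses:
            status_counts.setdefault(gs.gene, {"BAL": 0, "MAL": 0, "Intact": 0})
            status_counts[gs.gene][gs.status] += 1

    window_results = []
    if windows:
        tds_by_sample = {b.sample_id: b.tds for b in eligible}
        tdp_flags = {
            b.sample_id: b.tdp_call.tdp_status == "positive" for b in eligible
        }
        window_results = cohort_stats.td_window_enrichment(
            windows, tds_by_sample, tdp_flags, alpha=config.window_alpha
        )

    # multi-sample patients: flag genes with discordant allelic status
    # across a patient's tumors for manual review
    flagged = []
    status_by_patient: dict = {}
    for p, b in zip(profiles, bundles):
        if b.eligible:
            status_by_patient.setdefault(p.patient_id, []).append(
                {g.gene: g.status for g in b.gene_statuses}
            )
    for patient, per_sample in status_by_patient.items():
        if len(per_sample) < 2:
            continue
        for gene_name in per_sample[0]:
            if len({s[gene_name] for s in per_sample}) > 1:
                flagged.append((patient, gene_name))

    trees = {}
    by_patient: dict = {}
    for p, b in zip(profiles, bundles):
        if b.eligible:
            by_patient.setdefault(p.patient_id, {})[p.sample_id] = b.tds
    for patient, samples in by_patient.items():
        if len(samples) >= 2 and any(samples.values()):
            catalog = phylogeny.build_event_catalog(
                samples, patient_id=patient,
                min_overlap=config.min_reciprocal_overlap,
            )
            trees[patient] = phylogeny.to_newick(phylogeny.nj_tree(catalog))

    return CohortReport(
        config_hash=config.config_hash,
        n_samples=len(profiles),
        n_eligible=len(eligible),
        bundles=bundles,
        tdp_counts=tdp_counts,
        status_counts=status_counts,
        window_enrichment=window_results,
        trees=trees,
        flagged_for_review=flagged,
    )
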
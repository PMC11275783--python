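"""Cohort-level association statistics for TD-altered regions and genes.

Per 50 kb window the cohort is reduced to a 2x2 table of samples
with/without an overlapping TD by TDP status and tested with a
two-sided chi-square test of independence (Fisher's exact fallback when
any expected cell < 5), Bonferroni-corrected over windows. Oncogene
containment (gene fully inside a TD) and tumor-suppressor transection
(a TD boundary inside the gene) use two-sided Fisher's exact tests with
Bonferroni correction over genes. Mutual exclusivity between gene-level
BAL flags uses a one-tailed Fisher test toward depletion of
co-occurrence, and continuous group comparisons use the two-tailed
Mann-Whitney U test.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .model import GenomicInterval, TandemDuplication

WINDOW_ALPHA = 0.001  # Bonferroni-adjusted significance for windows
GENE_ALPHA = 0.01  # for oncogene / TSG tests
MIN_TDS_FOR_NEGATIVE_UNIVERSE = 2  # TDP- samples need > 1 simple TD


@dataclass
class EnrichmentResult:
    name: str
    count_tdp_pos: int
    n_tdp_pos: int
    count_tdp_neg: int
    n_tdp_neg: int
    odds_ratio: float
    p_value: float
    adjusted_p: float
    significant: bool
    test: str = "chi2"  # chi2 | fisher


def bonferroni(p: float, n_tests: int) -> float:
    return min(1.0, p * n_tests)


def _table_test(a: int, b: int, c: int, d: int, prefer_chi2: bool = True):
    """(odds_ratio, p, test_name) for the 2x2 table [[a, b], [c, d]].

    chi-square without continuity correction unless any expected count
    is < 5 (or a margin is zero), in which case Fisher's exact is used.
    A zero-margin table gets p = 1 by convention.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return odds, 1.0, "degenerate"
    if prefer_chi2:
        expected = stats.contingency.expected_freq(table)
        if (expected >= 5).all():
            _, p, _, _ = stats.chi2_contingency(table, correction=False)
            return odds, float(p), "chi2"
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds, float(p), "fisher"


def _sample_alteration_test(
    regions: Sequence[GenomicInterval],
    tds_by_sample: dict,
    tdp_status: dict,
    altered_fn,
    prefer_chi2: bool,
    alpha: float,
) -> list[EnrichmentResult]:
    pos = [s for s, flag in tdp_status.items() if flag]
    neg = [
        s
        for s, flag in tdp_status.items()
        if not flag and len(tds_by_sample.get(s, ())) >= MIN_TDS_FOR_NEGATIVE_UNIVERSE
    ]
    results = []
    n_tests = len(regions)
    for region in regions:
        hit_pos = sum(1 for s in pos if altered_fn(region, tds_by_sample.get(s, ())))
        hit_neg = sum(1 for s in neg if altered_fn(region, tds_by_sample.get(s, ())))
        odds, p, test = _table_test(
            hit_pos, len(pos) - hit_pos, hit_neg, len(neg) - hit_neg,
            prefer_chi2=prefer_chi2,
        )
        adj = bonferroni(p, n_tests)
        results.append(
            EnrichmentResult(
                name=region.name,
                count_tdp_pos=hit_pos,
                n_tdp_pos=len(pos),
                count_tdp_neg=hit_neg,
                n_tdp_neg=len(neg),
                odds_ratio=odds,
                p_value=p,
                adjusted_p=adj,
                significant=adj < alpha,
                test=test,
            )
        )
    return results


def _overlaps(region: GenomicInterval, tds) -> bool:
    return any(region.overlap(td.chrom, td.start, td.end) > 0 for td in tds)


def _contained(region: GenomicInterval, tds) -> bool:
    return any(
        td.chrom == region.chrom and td.start <= region.start and td.end >= region.end
        for td in tds
    )


def _transected(region: GenomicInterval, tds) -> bool:
    return any(
        region.contains(td.chrom, td.start) or region.contains(td.chrom, td.end)
        for td in tds
    )


def td_window_enrichment(
    windows: Sequence[GenomicInterval],
    tds_by_sample: dict,
    tdp_status: dict,
    alpha: float = WINDOW_ALPHA,
) -> list[EnrichmentResult]:
    """Per-window TD-overlap enrichment in TDP+ vs TDP- samples
    (chi-square with Fisher fallback, Bonferroni over windows)."""
    return _sample_alteration_test(
        windows, tds_by_sample, tdp_status, _overlaps, prefer_chi2=True, alpha=alpha
    )


def oncogene_containment_test(
    genes: Sequence[GenomicInterval],
    tds_by_sample: dict,
    tdp_status: dict,
    alpha: float = GENE_ALPHA,
) -> list[EnrichmentResult]:
    """Oncogene fully contained within a TD; Fisher + Bonferroni."""
    return _sample_alteration_test(
        genes, tds_by_sample, tdp_status, _contained, prefer_chi2=False, alpha=alpha
    )


def tsg_transection_test(
    genes: Sequence[GenomicInterval],
    tds_by_sample: dict,
    tdp_status: dict,
    alpha: float = GENE_ALPHA,
) -> list[EnrichmentResult]:
    """Tumor suppressor transected by a TD boundary; Fisher + Bonferroni."""
    return _sample_alteration_test(
        genes, tds_by_sample, tdp_status, _transected, prefer_chi2=False, alpha=alpha
    )


def mutual_exclusivity_test(status_a: Sequence[bool], status_b: Sequence[bool]):
    """One-tailed Fisher's exact test toward depletion of co-occurrence
    between two aligned per-sample BAL flag vectors; (odds_ratio, p)."""
    a = np.asarray(status_a, dtype=bool)
    b = np.asarray(status_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("flag vectors must be aligned")
    co = int((a & b).sum())
    a_only = int((a & ~b).sum())
    b_only = int((~a & b).sum())
    neither = int((~a & ~b).sum())
    odds, p = stats.fisher_exact(
        [[co, a_only], [b_only, neither]], alternative="less"
    )
    return float(odds), float(p)


def group_compare(values: Sequence[float], labels: Sequence) -> tuple:
    """Two-tailed Mann-Whitney U between the two label groups;
    (U, p)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError(f"need exactly two groups, got {groups.size}")
    x = values[labels == groups[0]]
    y = values[labels == groups[1]]
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def results_to_tsv(results: Iterable[EnrichmentResult]) -> str:
    lines = [
        "name\tcount_tdp_pos\tn_tdp_pos\tcount_tdp_neg\tn_tdp_neg\t"
        "odds_ratio\tp_value\tadjusted_p\tsignificant\ttest"
    ]
    for r in results:
        lines.append(
            f"{r.name}\t{r.count_tdp_pos}\t{r.n_tdp_pos}\t{r.count_tdp_neg}\t"
            f"{r.n_tdp_neg}\t{r.odds_ratio}\t{r.p_value}\t{r.adjusted_p}\t"
            f"{int(r.significant)}\t{r.test}"
        )
    return "\n".join(lines) + "\n"


def tile_windows(chrom_lengths: dict, size: int = 50_000) -> list[GenomicInterval]:
    """Tile the genome with fixed-size windows (last window clipped)."""
    out = []
    for chrom, length in chrom_lengths.items():
        start = 1
        i = 0
        while start <= length:
            end = min(start + size - 1, length)
            out.append(GenomicInterval(chrom, start, end, f"{chrom}:{start}", role="window"))
            start = end + 1
            i += 1
    return out
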
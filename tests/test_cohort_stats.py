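"""Exact-test agreement with enumeration oracles; enrichment logic."""
import itertools
from math import comb

import numpy as np
import pytest
from scipy import stats

from tdpscan.model import GenomicInterval, TandemDuplication
from tdpscan.cohort_stats import (
    bonferroni,
    group_compare,
    mutual_exclusivity_test,
    oncogene_containment_test,
    td_window_enrichment,
    tile_windows,
    tsg_transection_test,
)


def fisher_oracle(a, b, c, d, alternative):
    """Brute-force hypergeometric enumeration with fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    if alternative == "less":
        return sum(prob(x) for x in range(lo, a + 1))
    if alternative == "greater":
        return sum(prob(x) for x in range(a, hi + 1))
    pobs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= pobs * (1 + 1e-9))


def test_fisher_matches_enumeration_oracle():
    """All random tables with n <= 60, one- and two-sided, within 1e-10."""
    rng = np.random.default_rng(0)
    for _ in range(150):
        a, b, c, d = rng.integers(0, 15, 4)
        for alt in ("two-sided", "less", "greater"):
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alt)
            assert abs(p - fisher_oracle(a, b, c, d, alt)) < 1e-10, (a, b, c, d, alt)


def test_spec_toy_table_fisher():
    _, p = stats.fisher_exact([[8, 2], [1, 19]], alternative="two-sided")
    assert abs(p - fisher_oracle(8, 2, 1, 19, "two-sided")) < 1e-10


def mwu_oracle(x, y):
    """Exact permutation enumeration of the two-sided Mann-Whitney p."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum((xi > np.asarray(y)).sum() + 0.5 * (xi == np.asarray(y)).sum()
                for xi in x)
    us = []
    for combi in itertools.combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), bool)
        mask[list(combi)] = True
        xx, yy = pooled[mask], pooled[~mask]
        us.append(sum((xi > yy).sum() + 0.5 * (xi == yy).sum() for xi in xx))
    us = np.asarray(us)
    return min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))


def test_mann_whitney_exact_against_permutation_oracle():
    for seed in range(5):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=5)
        y = rng.normal(0.8, 1.0, size=5)
        values = np.concatenate([x, y])
        labels = [0] * 5 + [1] * 5
        _, p = group_compare(values, labels)
        assert abs(p - mwu_oracle(x, y)) < 1e-10


def test_group_compare_fully_separated():
    values = [1, 2, 3, 4, 5, 10, 11, 12, 13, 14]
    labels = ["a"] * 5 + ["b"] * 5
    _, p = group_compare(values, labels)
    assert p == pytest.approx(2 / comb(10, 5), abs=1e-12)


def test_group_compare_identical_groups():
    values = [1.0, 2.0, 3.0] * 2
    labels = [0, 0, 0, 1, 1, 1]
    _, p = group_compare(values, labels)
    assert p == pytest.approx(1.0)
    with pytest.raises(ValueError):
        group_compare([1, 2], [0, 0])


def test_group_compare_power_increases_with_shift():
    rng = np.random.default_rng(1)
    pvals = []
    for shift in (0.0, 1.0, 3.0):
        ps = []
        for _ in range(30):
            x = rng.normal(size=12)
            y = rng.normal(shift, 1.0, size=12)
            _, p = group_compare(np.concatenate([x, y]), [0] * 12 + [1] * 12)
            ps.append(p)
        pvals.append(np.mean(ps))
    assert pvals[0] > pvals[1] > pvals[2]


# ---------------------------------------------------------------------------
# mutual exclusivity


def test_mutual_exclusivity_exact_tail():
    """co=0, A-only=39, B-only=69, neither=724 -> hypergeometric tail."""
    a = [True] * 39 + [False] * (69 + 724)
    b = [False] * 39 + [True] * 69 + [False] * 724
    _, p = mutual_exclusivity_test(a, b)
    assert abs(p - fisher_oracle(0, 39, 69, 724, "less")) < 1e-12
    assert p < 0.05


def test_mutual_exclusivity_direction():
    # zero co-occurrence with abundant marginals -> small p
    a = [True] * 20 + [False] * 20
    b = [False] * 20 + [True] * 20
    _, p = mutual_exclusivity_test(a, b)
    assert p < 1e-6


def test_mutual_exclusivity_null_uniform():
    rng = np.random.default_rng(2)
    ps = []
    for _ in range(200):
        a = rng.random(60) < 0.3
        b = rng.random(60) < 0.3
        ps.append(mutual_exclusivity_test(a, b)[1])
    # one-sided null p-values are stochastically >= uniform
    assert np.mean(ps) > 0.4


# ---------------------------------------------------------------------------
# enrichment


def td(chrom, start, end):
    return TandemDuplication(chrom, start, end, 3, 2, 2)


def cohort_with_hot_window():
    """40/46 TDP+ samples hit the first window; 0/777 TDP- do."""
    tds_by_sample = {}
    status = {}
    for i in range(46):
        sid = f"P{i}"
        hits = [td("chr1", 10_000, 20_000)] if i < 40 else [td("chr1", 900_000, 910_000)]
        tds_by_sample[sid] = hits + [td("chr2", 5_000, 9_000), td("chr2", 50_000, 60_000)]
        status[sid] = True
    for i in range(777):
        sid = f"N{i}"
        tds_by_sample[sid] = [td("chr2", 100_000, 104_000), td("chr2", 300_000, 304_000)]
        status[sid] = False
    return tds_by_sample, status


def test_window_enrichment_detects_hot_window():
    windows = tile_windows({"chr1": 200_000}, size=50_000)
    tds_by_sample, status = cohort_with_hot_window()
    results = td_window_enrichment(windows, tds_by_sample, status)
    hot = results[0]
    assert hot.count_tdp_pos == 40 and hot.count_tdp_neg == 0
    assert hot.significant and hot.adjusted_p < 0.001
    assert not any(r.significant for r in results[1:])


def test_window_identical_frequencies_not_significant():
    windows = [GenomicInterval("chr1", 1, 50_000, "w0", role="window")]
    tds_by_sample = {}
    status = {}
    for i in range(20):
        tds_by_sample[f"S{i}"] = [td("chr1", 100, 200), td("chr1", 5_000, 6_000)]
        status[f"S{i}"] = i < 10
    results = td_window_enrichment(windows, tds_by_sample, status)
    assert results[0].odds_ratio in (1.0, np.inf) or np.isnan(results[0].odds_ratio)
    assert results[0].p_value == 1.0


def test_tdp_negative_universe_requires_two_tds():
    windows = [GenomicInterval("chr1", 1, 50_000, "w0", role="window")]
    tds_by_sample = {"A": [td("chr1", 100, 200), td("chr1", 900, 950)],
                     "B": [td("chr1", 100, 200)],  # only 1 TD: excluded
                     "C": [td("chr2", 100, 200), td("chr2", 900, 950)]}
    status = {"A": True, "B": False, "C": False}
    results = td_window_enrichment(windows, tds_by_sample, status)
    assert results[0].n_tdp_neg == 1  # only C counted


def test_null_simulation_no_significant_windows():
    """No enrichment signal: 0 significant windows at adjusted p<0.001
    in >= 95% of replicates."""
    windows = tile_windows({"chr1": 2_000_000}, size=50_000)  # 40 windows
    bad = 0
    for rep in range(20):
        rng = np.random.default_rng(rep)
        tds_by_sample, status = {}, {}
        for i in range(60):
            sid = f"S{i}"
            starts = rng.integers(1, 1_900_000, size=3)
            tds_by_sample[sid] = [td("chr1", int(s), int(s) + 5_000) for s in starts]
            status[sid] = i < 20
        results = td_window_enrichment(windows, tds_by_sample, status)
        if any(r.significant for r in results):
            bad += 1
    assert bad <= 1


def test_oncogene_containment_vs_transection():
    gene = GenomicInterval("chr1", 100_000, 150_000, "ONC", role="oncogene")
    contained = {"A": [td("chr1", 50_000, 200_000)]}   # gene inside TD
    straddle = {"A": [td("chr1", 120_000, 200_000)]}   # boundary inside gene
    status = {"A": True}
    r = oncogene_containment_test([gene], contained, status)
    assert r[0].count_tdp_pos == 1
    r = oncogene_containment_test([gene], straddle, status)
    assert r[0].count_tdp_pos == 0
    r = tsg_transection_test([gene], straddle, status)
    assert r[0].count_tdp_pos == 1
    r = tsg_transection_test([gene], contained, status)
    assert r[0].count_tdp_pos == 0


def test_fisher_used_for_gene_tests_matches_oracle():
    gene = GenomicInterval("chr1", 100_000, 150_000, "ONC", role="oncogene")
    tds_by_sample, status = {}, {}
    for i in range(10):
        hit = i < 8
        tds_by_sample[f"P{i}"] = (
            [td("chr1", 50_000, 200_000)] if hit else [td("chr1", 10_000, 20_000)]
        ) + [td("chr2", 1_000, 2_000)]
        status[f"P{i}"] = True
    for i in range(20):
        hit = i < 1
        tds_by_sample[f"N{i}"] = (
            [td("chr1", 50_000, 200_000)] if hit else [td("chr1", 10_000, 20_000)]
        ) + [td("chr2", 1_000, 2_000)]
        status[f"N{i}"] = False
    r = oncogene_containment_test([gene], tds_by_sample, status)[0]
    assert r.test == "fisher"
    assert abs(r.p_value - fisher_oracle(8, 2, 1, 19, "two-sided")) < 1e-10


def test_bonferroni_monotone_and_capped():
    assert bonferroni(0.5, 3) == 1.0
    assert bonferroni(0.01, 5) == pytest.approx(0.05)
    ps = sorted(np.random.default_rng(0).random(20))
    adj = [bonferroni(p, 20) for p in ps]
    assert all(a <= b for a, b in zip(adj, adj[1:]))
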
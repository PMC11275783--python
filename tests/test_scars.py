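"""LOH score, signature-exposure fitting, HRD-signature gating."""
import numpy as np
import pytest

from tdpscan.model import CopyNumberSegment, GenomicInterval
from tdpscan.scars import (
    fit_signature_exposures,
    hrd_signature_call,
    loh_score,
    scar_report,
)
from tdpscan.synthetic import make_signature_matrix, simulate_mutation_catalog


def arms_100_90():
    return [
        GenomicInterval("chr1", 1, 100_000_000, "chr1p", role="arm"),
        GenomicInterval("chr2", 1, 90_000_000, "chr2p", role="arm"),
    ]


def test_loh_score_zero_without_loh(simple_arm):
    segs = [CopyNumberSegment("chr1", 1, 50_000_000, 2, 1)]
    score, excluded = loh_score(segs, simple_arm)
    assert score == 0.0 and excluded == []


def test_loh_score_direct_ratio(simple_arm):
    segs = [
        CopyNumberSegment("chr1", 1, 30_000_000, 2, 0),
        CopyNumberSegment("chr1", 30_000_001, 100_000_000, 2, 1),
    ]
    score, excluded = loh_score(segs, simple_arm)
    assert score == pytest.approx(0.30)
    assert excluded == []


def test_loh_score_arm_exclusion_rule():
    """An arm with 80% LOH is dropped from numerator and denominator:
    10 Mb LOH of the remaining 90 Mb gives 10/90."""
    segs = [
        # chr1p: fully covered, 80 Mb of 100 Mb LOH -> excluded
        CopyNumberSegment("chr1", 1, 80_000_000, 2, 0),
        CopyNumberSegment("chr1", 80_000_001, 100_000_000, 2, 1),
        # chr2p: fully covered (90 Mb), 10 Mb LOH
        CopyNumberSegment("chr2", 1, 10_000_000, 1, 0),
        CopyNumberSegment("chr2", 10_000_001, 90_000_000, 2, 1),
    ]
    score, excluded = loh_score(segs, arms_100_90())
    assert excluded == ["chr1p"]
    assert score == pytest.approx(10 / 90)


def test_loh_score_invariant_under_segment_splitting(simple_arm):
    segs = [
        CopyNumberSegment("chr1", 1, 30_000_000, 2, 0),
        CopyNumberSegment("chr1", 30_000_001, 100_000_000, 2, 1),
    ]
    halves = [
        CopyNumberSegment("chr1", 1, 15_000_000, 2, 0),
        CopyNumberSegment("chr1", 15_000_001, 30_000_000, 2, 0),
        CopyNumberSegment("chr1", 30_000_001, 60_000_000, 2, 1),
        CopyNumberSegment("chr1", 60_000_001, 100_000_000, 2, 1),
    ]
    assert loh_score(segs, simple_arm)[0] == loh_score(halves, simple_arm)[0]


def test_loh_score_sex_chromosome_excluded_by_default():
    arms = [
        GenomicInterval("chr1", 1, 100_000_000, "chr1p", role="arm"),
        GenomicInterval("chrX", 1, 100_000_000, "Xp", role="arm"),
    ]
    segs = [
        CopyNumberSegment("chr1", 1, 100_000_000, 2, 1),
        CopyNumberSegment("chrX", 1, 50_000_000, 1, 0),
    ]
    score, _ = loh_score(segs, arms)
    assert score == 0.0


def test_loh_score_empty_segments_undefined(simple_arm):
    score, _ = loh_score([], simple_arm)
    assert score is None


def test_homozygous_deletion_not_counted_as_loh(simple_arm):
    # minor 0 with total 0 is absence, not LOH of a retained allele
    segs = [
        CopyNumberSegment("chr1", 1, 10_000_000, 0, 0),
        CopyNumberSegment("chr1", 10_000_001, 100_000_000, 2, 1),
    ]
    assert loh_score(segs, simple_arm)[0] == 0.0


# ---------------------------------------------------------------------------
# exposures


def grid_search_two_sig(catalog, sig_matrix, cols, step=1e-4):
    """Brute-force oracle: scan the mixing fraction of a two-signature
    fit, profiling out the overall scale by least-squares projection."""
    w = sig_matrix[list(cols)].to_numpy()
    best = None
    for f in np.arange(0, 1 + step, step):
        direction = f * w[:, 0] + (1 - f) * w[:, 1]
        scale = float(catalog @ direction) / float(direction @ direction)
        sse = ((catalog - scale * direction) ** 2).sum()
        if best is None or sse < best[1]:
            best = (f, sse)
    return best[0]


def test_single_signature_catalog_recovered(sig_matrix):
    catalog = 1000 * sig_matrix["SBS3"].to_numpy()
    exp = fit_signature_exposures(catalog, sig_matrix)
    assert exp["SBS3"] == pytest.approx(1000, rel=1e-6)
    assert exp.drop("SBS3").abs().max() < 1e-6


def test_two_signature_fit_matches_grid_oracle(sig_matrix):
    rng = np.random.default_rng(5)
    two = sig_matrix[["SBS3", "SBS8"]]
    catalog = simulate_mutation_catalog([0.7, 0.3], 5000, two, rng)
    exp = fit_signature_exposures(catalog, two)
    f_nnls = exp["SBS3"] / exp.sum()
    f_grid = grid_search_two_sig(catalog, sig_matrix, ("SBS3", "SBS8"))
    assert f_nnls == pytest.approx(f_grid, abs=1e-3)


def test_mixture_recovery_rmse(sig_matrix):
    """0.6/0.4 mixes at n=5000: proportions recovered within 0.05 RMSE."""
    errs = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        catalog = simulate_mutation_catalog(
            [0.0, 0.6, 0.0, 0.4], 5000, sig_matrix, rng
        )
        exp = fit_signature_exposures(catalog, sig_matrix)
        props = exp / exp.sum()
        errs.append((props["SBS3"] - 0.6) ** 2)
        errs.append((props["SBS8"] - 0.4) ** 2)
    assert np.sqrt(np.mean(errs)) < 0.05


def test_orthogonal_catalog_reports_near_zero_exposures(sig_matrix):
    # mass on channels where every signature is (numerically) tiny
    weight = sig_matrix.sum(axis=1).to_numpy()
    catalog = np.zeros(96)
    catalog[np.argsort(weight)[:3]] = 100
    exp = fit_signature_exposures(catalog, sig_matrix)
    assert exp.sum() < 0.25 * catalog.sum()


def test_zero_catalog_rejected(sig_matrix):
    with pytest.raises(ValueError):
        fit_signature_exposures(np.zeros(96), sig_matrix)


# ---------------------------------------------------------------------------
# HRD gates


def exposures(sbs3=0.0, sbs8=0.0):
    import pandas as pd

    return pd.Series({"SBS1": 0.0, "SBS3": sbs3, "SBS5": 0.0, "SBS8": sbs8})


@pytest.mark.parametrize(
    "n_snvs,sbs3,sbs8,prop,call",
    [
        (40, 40, 0, 1.0, "unevaluable"),         # <= 50 SNVs
        (50, 50, 0, 1.0, "unevaluable"),         # boundary: strict >50
        (51, 51, 0, 1.0, "yes"),
        (100, 2, 2, 0.04, "no"),                 # 0.04 <= 0.05
        (100, 5, 0, 0.05, "no"),                 # exactly 0.05: strict >
        (100, 5, 1, 0.06, "yes"),
        (200, 200, 0, 1.0, "yes"),
    ],
)
def test_hrd_signature_gates(n_snvs, sbs3, sbs8, prop, call):
    got_prop, got_call = hrd_signature_call(exposures(sbs3, sbs8), n_snvs)
    assert got_prop == pytest.approx(prop)
    assert got_call == call


def test_pure_sbs3_mode():
    prop, call = hrd_signature_call(exposures(sbs3=4, sbs8=90), 100,
                                    signatures=("SBS3",))
    assert prop == pytest.approx(0.04) and call == "no"


def test_missing_signature_rejected():
    import pandas as pd

    with pytest.raises(ValueError, match="SBS8"):
        hrd_signature_call(pd.Series({"SBS3": 1.0}), 100)


def test_scar_report_combines_both_metrics(simple_arm, sig_matrix):
    segs = [
        CopyNumberSegment("chr1", 1, 30_000_000, 2, 0),
        CopyNumberSegment("chr1", 30_000_001, 100_000_000, 2, 1),
    ]
    rng = np.random.default_rng(0)
    catalog = simulate_mutation_catalog([0, 1.0, 0, 0], 200, sig_matrix, rng)
    rep = scar_report("S1", segs, simple_arm, catalog, sig_matrix)
    assert rep.loh_score == pytest.approx(0.30)
    assert rep.n_snvs == 200
    assert rep.hrd_signature_present == "yes"
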
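"""Homologous-recombination-deficiency scar metrics.

Two scars are scored per sample:

* **LOH score** — the fraction of the covered genome on segments with
  minor allele copy number 0, after excluding chromosome arms whose
  merged LOH coverage exceeds 75% of the arm (whole-arm LOH reflects
  non-HRD mechanisms). Sex chromosomes are excluded by default.
* **HRD mutational-signature proportion** — single-base-substitution
  exposures are fit to a 96-channel signature reference by non-negative
  least squares; the SBS3 + SBS8 exposure counts divided by the SNV
  total give the HRD-signature proportion. Samples with <= 50 passing
  SNVs are unevaluable; presence requires a proportion > 0.05.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io import SEX_CHROMS
from .model import CopyNumberSegment, GenomicInterval, merge_intervals

ARM_LOH_EXCLUSION = 0.75  # arms with merged LOH fraction > this are dropped
MIN_SNVS = 50  # strict: evaluable requires n_snvs > 50
HRD_PROPORTION_THRESHOLD = 0.05  # strict >
HRD_SIGNATURES = ("SBS3", "SBS8")


@dataclass
class ScarReport:
    sample_id: str
    loh_score: Optional[float]
    excluded_arms: list = field(default_factory=list)
    n_snvs: int = 0
    exposures: Optional[pd.Series] = None  # mutation counts per signature
    hrd_signature_proportion: Optional[float] = None
    hrd_signature_present: str = "unevaluable"  # yes | no | unevaluable


def loh_score(
    segments: Iterable[CopyNumberSegment],
    arms: Iterable[GenomicInterval],
    arm_exclusion: float = ARM_LOH_EXCLUSION,
    exclude_sex_chroms: bool = True,
):
    """(score, excluded_arms) over arm-clipped segments.

    score = LOH segment length / total segment length on retained arms;
    an arm is excluded when its merged LOH coverage exceeds
    ``arm_exclusion`` of the arm length. Returns (None, excluded) when
    no covered bases remain.
    """
    arms = [a for a in arms if not (exclude_sex_chroms and a.chrom in SEX_CHROMS)]
    per_arm: dict[str, dict] = {
        a.name: {"arm": a, "loh": [], "covered": 0, "loh_len": 0} for a in arms
    }
    for seg in segments:
        for a in arms:
            ov = a.overlap(seg.chrom, seg.start, seg.end)
            if ov == 0:
                continue
            rec = per_arm[a.name]
            rec["covered"] += ov
            if seg.is_loh:
                lo = max(seg.start, a.start)
                hi = min(seg.end, a.end)
                rec["loh"].append((lo, hi))
                rec["loh_len"] += ov

    excluded = []
    num = 0
    den = 0
    for name, rec in per_arm.items():
        _, merged_len = merge_intervals(rec["loh"])
        if merged_len / rec["arm"].length > arm_exclusion:
            excluded.append(name)
            continue
        num += rec["loh_len"]
        den += rec["covered"]
    if den == 0:
        return None, excluded
    return num / den, excluded


def fit_signature_exposures(catalog, signature_matrix: pd.DataFrame) -> pd.Series:
    """Non-negative least-squares refit of a 96-channel catalog onto the
    signature reference; exposures returned in mutation counts."""
    v = np.asarray(catalog, dtype=float)
    if v.ndim != 1 or v.shape[0] != signature_matrix.shape[0]:
        raise ValueError("catalog must be a vector over the matrix channels")
    if v.sum() <= 0:
        raise ValueError("catalog total must be positive")
    w = signature_matrix.to_numpy(dtype=float)
    coef, _residual = nnls(w, v)
    return pd.Series(coef, index=signature_matrix.columns)


def hrd_signature_call(
    exposures: pd.Series,
    n_snvs: int,
    signatures: tuple = HRD_SIGNATURES,
    min_snvs: int = MIN_SNVS,
    threshold: float = HRD_PROPORTION_THRESHOLD,
):
    """(proportion, call): combined signature counts over the SNV total.

    call is 'unevaluable' when n_snvs <= min_snvs, else 'yes' iff the
    proportion strictly exceeds the threshold. Pass
    ``signatures=("SBS3",)`` for the pure-SBS3 variant.
    """
    present = [s for s in signatures if s in exposures.index]
    if len(present) != len(signatures):
        missing = set(signatures) - set(present)
        raise ValueError(f"exposures missing signatures: {sorted(missing)}")
    proportion = float(sum(exposures[s] for s in signatures)) / n_snvs if n_snvs else 0.0
    if n_snvs <= min_snvs:
        return proportion, "unevaluable"
    return proportion, ("yes" if proportion > threshold else "no")


def scar_report(
    sample_id: str,
    segments,
    arms,
    catalog,
    signature_matrix: Optional[pd.DataFrame],
    n_snvs: Optional[int] = None,
) -> ScarReport:
    """Convenience wrapper combining both scars for one sample."""
    score, excluded = loh_score(segments, arms)
    report = ScarReport(sample_id=sample_id, loh_score=score, excluded_arms=excluded)
    total = int(np.sum(catalog)) if catalog is not None else 0
    report.n_snvs = n_snvs if n_snvs is not None else total
    if total > 0 and signature_matrix is not None:
        report.exposures = fit_signature_exposures(catalog, signature_matrix)
        prop, call = hrd_signature_call(report.exposures, report.n_snvs)
        report.hrd_signature_proportion = prop
        report.hrd_signature_present = call
    return report
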
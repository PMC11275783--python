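"""Tandem-duplicator phenotype (TDP) classification.

The spatial dispersion of a sample's TDs is summarised by the
nearest-neighbor index (NNI): the ratio of the observed mean
nearest-neighbor distance between TD midpoints to the expectation under
uniform (1-D Poisson) placement, L/(2n) per chromosome, pooled across
chromosomes with an n-weighted mean. NNI ~ 1 for random placement,
<< 1 for clustered, -> 2 for perfectly regular spacing.

A sample is TDP-positive when its NNI exceeds the platform threshold
(WES > 1, WGS > 1.25) and the median TD length exceeds 100 kb.

TDP-positive samples are assigned a size group by fitting 1-4 component
Gaussian mixtures to log10(TD length in kb), selecting by BIC, dropping
components with weight <= 0.1, and mapping the surviving component
means onto length bins: [0,2) -> 1-100 kb, [2,3) -> 100 kb-1 Mb,
[3,4] -> 1-10 Mb. Single bins give Groups 1-3; the pairs give Group 4
(1+2), Group 5 (1+3), Group 6 (2+3).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from sklearn.mixture import GaussianMixture

from .model import TandemDuplication

NNI_THRESHOLD = {"WES": 1.0, "WGS": 1.25}
MEDIAN_LENGTH_THRESHOLD = 100_000  # bp, strict >
MIN_LENGTHS_FOR_GMM = 5
WEIGHT_FLOOR = 0.1  # components with weight <= this are dropped

_GROUP_BY_BINS = {
    frozenset({1}): 1,
    frozenset({2}): 2,
    frozenset({3}): 3,
    frozenset({1, 2}): 4,
    frozenset({1, 3}): 5,
    frozenset({2, 3}): 6,
}


@dataclass
class TDPCall:
    sample_id: str
    n_tds: int
    nni: Optional[float]
    median_td_length: Optional[float]
    tdp_status: str  # positive | negative | unevaluable
    size_group: Optional[int] = None


@dataclass
class SizeGroupModel:
    """All candidate mixture solutions plus the selected one."""

    n_components: int
    means: np.ndarray  # log10(kb), selected solution
    variances: np.ndarray
    weights: np.ndarray
    bic: dict = field(default_factory=dict)  # k -> BIC
    retained: list = field(default_factory=list)  # indices surviving weight filter
    bins: list = field(default_factory=list)  # length bin per retained component
    group: Optional[int] = None


def compute_nni(tds: Iterable[TandemDuplication], chrom_lengths: dict) -> Optional[float]:
    """Pooled nearest-neighbor index over chromosomes with >= 2 TDs.

    Returns None (sample unevaluable) when no chromosome has two TDs.
    Invariant under joint rescaling of coordinates and lengths.
    """
    mids: dict[str, list[float]] = {}
    for td in tds:
        mids.setdefault(td.chrom, []).append(td.midpoint)

    num = 0.0
    weight = 0
    for chrom, points in mids.items():
        n = len(points)
        if n < 2 or chrom not in chrom_lengths:
            continue
        pts = np.sort(np.asarray(points, dtype=float))
        gaps = np.diff(pts)
        nn = np.empty(n)
        nn[0] = gaps[0]
        nn[-1] = gaps[-1]
        if n > 2:
            nn[1:-1] = np.minimum(gaps[:-1], gaps[1:])
        observed = float(nn.mean())
        expected = chrom_lengths[chrom] / (2.0 * n)
        num += n * (observed / expected)
        weight += n
    if weight == 0:
        return None
    return num / weight


def classify_tdp(
    tds: list[TandemDuplication],
    platform: str,
    chrom_lengths: dict,
    sample_id: str = "",
    nni_thresholds: Optional[dict] = None,
    median_length_threshold: int = MEDIAN_LENGTH_THRESHOLD,
) -> TDPCall:
    """Platform-thresholded TDP call (no size group; see
    :func:`fit_size_group`)."""
    thresholds = nni_thresholds or NNI_THRESHOLD
    if platform not in thresholds:
        raise ValueError(f"unknown platform {platform!r}")
    nni = compute_nni(tds, chrom_lengths)
    median_len = float(np.median([td.length for td in tds])) if tds else None
    if nni is None:
        status = "unevaluable"
    elif nni > thresholds[platform] and median_len > median_length_threshold:
        status = "positive"
    else:
        status = "negative"
    return TDPCall(
        sample_id=sample_id,
        n_tds=len(tds),
        nni=nni,
        median_td_length=median_len,
        tdp_status=status,
    )


def _bin_of(mean_log10kb: float) -> Optional[int]:
    """Length bin of a component mean; boundary values go to the higher
    bin; means outside [0, 4] are unmapped."""
    if mean_log10kb < 0 or mean_log10kb > 4:
        return None
    if mean_log10kb < 2:
        return 1
    if mean_log10kb < 3:
        return 2
    return 3


def fit_size_group(
    td_lengths: Iterable[float],
    seed: int = 0,
    max_components: int = 4,
    weight_floor: float = WEIGHT_FLOOR,
    variance_ceiling: Optional[float] = None,
    min_lengths: int = MIN_LENGTHS_FOR_GMM,
) -> SizeGroupModel:
    """Gaussian-mixture size grouping of TD lengths (bp).

    Fits 1..``max_components`` mixtures on log10(length/1000), selects
    by BIC (ties toward fewer components), drops components with weight
    <= ``weight_floor`` (and, optionally, variance above
    ``variance_ceiling``), then maps retained means to the group label.
    """
    lengths = np.asarray(list(td_lengths), dtype=float)
    if lengths.size < min_lengths:
        raise ValueError(f"need >= {min_lengths} TD lengths, got {lengths.size}")
    if (lengths <= 0).any():
        raise ValueError("TD lengths must be positive")
    x = np.log10(lengths / 1000.0).reshape(-1, 1)

    best = None
    bics: dict[int, float] = {}
    for k in range(1, max_components + 1):
        if k > lengths.size:
            break
        with warnings.catch_warnings():
            # over-parameterized candidate solutions may hit max_iter;
            # they lose the BIC comparison anyway
            warnings.simplefilter("ignore")
            gm = GaussianMixture(
                n_components=k,
                covariance_type="full",
                n_init=10,
                init_params="kmeans",
                tol=1e-6,
                max_iter=500,
                reg_covar=1e-6,
                random_state=seed,
            ).fit(x)
        bic = float(gm.bic(x))
        bics[k] = bic
        if best is None or bic < best[1]:  # strict <: ties keep fewer components
            best = (gm, bic)

    gm = best[0]
    means = gm.means_.ravel()
    variances = gm.covariances_.reshape(-1)
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    means, variances, weights = means[order], variances[order], weights[order]

    retained = [
        i
        for i in range(len(means))
        if weights[i] > weight_floor
        and (variance_ceiling is None or variances[i] <= variance_ceiling)
    ]
    bins = []
    for i in retained:
        b = _bin_of(means[i])
        if b is not None:
            bins.append(b)
    group = _GROUP_BY_BINS.get(frozenset(bins))
    if not bins:
        warnings.warn("all retained component means fall outside [0, 4] log10(kb)")
    elif group is None:
        warnings.warn(f"no group defined for length-bin combination {sorted(set(bins))}")
    return SizeGroupModel(
        n_components=gm.n_components,
        means=means,
        variances=variances,
        weights=weights,
        bic=bics,
        retained=retained,
        bins=bins,
        group=group,
    )
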
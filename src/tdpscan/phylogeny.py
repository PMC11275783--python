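"""Multi-tumor TD phylogenies.

TDs from all tumors of one patient are merged into a unified event
catalog: events from different samples describe the same duplication
when they reciprocally overlap >= 0.9 of each other's width
(single-linkage, position-ordered, deterministic). The resulting
samples x events presence matrix yields pairwise Manhattan distances
(= number of discordant events) and a neighbor-joining tree rooted at
an all-absent "normal" pseudo-sample representing the germline state.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

MIN_RECIPROCAL_OVERLAP = 0.9


@dataclass
class TDEventCatalog:
    patient_id: str
    events: list  # (chrom, start, end) representative intervals
    presence: pd.DataFrame  # samples x events, bool
    sharing: dict  # "private"/"pairwise"/"triplet"/.../"all" -> counts


def _reciprocal_overlap(a, b) -> float:
    """min of the two mutual overlap fractions; 0 across chromosomes."""
    if a[0] != b[0]:
        return 0.0
    ov = min(a[2], b[2]) - max(a[1], b[1]) + 1
    if ov <= 0:
        return 0.0
    return min(ov / (a[2] - a[1] + 1), ov / (b[2] - b[1] + 1))


def build_event_catalog(
    tds_by_sample: dict,
    patient_id: str = "",
    min_overlap: float = MIN_RECIPROCAL_OVERLAP,
    reciprocal: bool = True,
) -> TDEventCatalog:
    """Merge per-sample TD lists into a unified catalog with a boolean
    presence matrix. ``tds_by_sample`` maps sample id to a list of
    objects with chrom/start/end (e.g. TandemDuplication).

    Events are clustered single-linkage under the (reciprocal) overlap
    rule after sorting by genomic position, so the result is invariant
    to sample order.
    """
    if len(tds_by_sample) < 2:
        raise ValueError("need >= 2 samples from one patient")
    records = []  # (chrom, start, end, sample)
    for sample, tds in tds_by_sample.items():
        for td in tds:
            records.append((td.chrom, td.start, td.end, sample))
    records.sort(key=lambda r: (r[0], r[1], r[2]))

    def linked(a, b) -> bool:
        if a[0] != b[0]:
            return False
        ov = min(a[2], b[2]) - max(a[1], b[1]) + 1
        if ov <= 0:
            return False
        fa = ov / (a[2] - a[1] + 1)
        fb = ov / (b[2] - b[1] + 1)
        return min(fa, fb) >= min_overlap if reciprocal else max(fa, fb) >= min_overlap

    clusters: list[list] = []
    for rec in records:
        placed = False
        for cluster in clusters:
            if any(linked(rec, member) for member in cluster):
                cluster.append(rec)
                placed = True
                break
        if placed:
            continue
        clusters.append([rec])

    samples = sorted(tds_by_sample)
    events = []
    matrix = np.zeros((len(samples), len(clusters)), dtype=bool)
    for j, cluster in enumerate(clusters):
        rep = min(cluster, key=lambda r: (r[0], r[1], r[2]))
        events.append((rep[0], rep[1], rep[2]))
        for rec in cluster:
            matrix[samples.index(rec[3]), j] = True

    presence = pd.DataFrame(
        matrix,
        index=samples,
        columns=[f"{c}:{s}-{e}" for c, s, e in events],
    )
    counts = matrix.sum(axis=0)
    sharing = {"private": int((counts == 1).sum()), "all": int((counts == len(samples)).sum())}
    for k in range(2, len(samples) + 1):
        sharing[f"shared_{k}"] = int((counts == k).sum())
    return TDEventCatalog(
        patient_id=patient_id, events=events, presence=presence, sharing=sharing
    )


def manhattan_distances(presence: pd.DataFrame, add_root: Optional[str] = "normal"):
    """Pairwise Manhattan distances on presence rows, optionally with an
    all-absent outgroup row appended."""
    mat = presence.to_numpy(dtype=float)
    ids = list(presence.index)
    if add_root is not None:
        mat = np.vstack([mat, np.zeros(mat.shape[1])])
        ids = ids + [add_root]
    dm = squareform(pdist(mat, metric="cityblock"))
    return DistanceMatrix(dm, ids=ids)


def nj_tree(
    catalog: TDEventCatalog,
    root_name: str = "normal",
) -> TreeNode:
    """Neighbor-joining tree on Manhattan distances between presence
    rows, rooted at an all-absent germline outgroup. Two samples give a
    single-edge (star) tree."""
    if catalog.presence.shape[0] < 2:
        raise ValueError("need >= 2 samples for a tree")
    dm = manhattan_distances(catalog.presence, add_root=root_name)
    tree = nj(dm)
    try:
        tip = tree.find(root_name)
        tree = tree.root_at(tip.parent)
    except Exception:  # rooting is cosmetic; keep the unrooted tree
        pass
    return tree


def to_newick(tree: TreeNode) -> str:
    return str(tree).strip()
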
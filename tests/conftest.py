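import numpy as np
import pytest

from tdpscan.model import CopyNumberSegment, GenomicInterval
from tdpscan.synthetic import (
    arms_from_layout,
    default_genome_layout,
    make_signature_matrix,
)


@pytest.fixture(scope="session")
def layout():
    return default_genome_layout()


@pytest.fixture(scope="session")
def arms(layout):
    return arms_from_layout(layout)


@pytest.fixture(scope="session")
def chrom_lengths(layout):
    return {c: L for c, L, _ in layout}


@pytest.fixture(scope="session")
def sig_matrix():
    return make_signature_matrix()


@pytest.fixture
def simple_arm():
    """One 100 Mb arm for constructed segment sets."""
    return [GenomicInterval("chr1", 1, 100_000_000, "chr1p", role="arm")]


def make_segments(chrom, pieces, cf=1.0):
    """pieces: list of (start, end, total, minor)."""
    return [
        CopyNumberSegment(chrom, s, e, t, m, cf) for s, e, t, m in pieces
    ]


@pytest.fixture
def seg_builder():
    return make_segments
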
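import numpy as np
import pandas as pd
import pytest

from cistrodyn.core import GenomeModel, GenomicInterval, Peak, PeakSet
from cistrodyn.occupancy import OccupancyMatrix, SampleMeta


@pytest.fixture
def genome():
    return GenomeModel({"chr1": 100_000, "chr2": 50_000})


def make_peak(chrom, start, end, summit=None, score=0.0, name="."):
    iv = GenomicInterval(chrom, start, end)
    if summit is None:
        summit = (end - start) // 2
    return Peak(iv, summit, score, name)


@pytest.fixture
def peak_factory():
    return make_peak


def peakset(*triples, **kw):
    return PeakSet([make_peak(*t) for t in triples], **kw)


@pytest.fixture
def peakset_factory():
    return peakset


@pytest.fixture
def small_matrix():
    """4 regions x 2 samples with deliberate rank structure and a tie."""
    values = pd.DataFrame(
        {"s1": [1.0, 2.0, 2.0, 8.0], "s2": [2.0, 3.0, 5.0, 9.0]},
        index=["r1", "r2", "r3", "r4"],
    )
    samples = {
        "s1": SampleMeta("s1", "TF", 0.0, "a", 1_000_000),
        "s2": SampleMeta("s2", "TF", 0.0, "b", 1_000_000),
    }
    return OccupancyMatrix(values, samples)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
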
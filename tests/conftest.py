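import numpy as np
import pytest

from rigstruct.genome import GenomeModel, load_default_genome
from rigstruct.model import CNSegment


@pytest.fixture(scope="session")
def genome():
    return load_default_genome()


@pytest.fixture(scope="session")
def toy_genome():
    """150 Mb chromosome with a 60 Mb p arm and a 90 Mb q arm."""
    return GenomeModel({"chr1": 150_000_000}, {"chr1": 60_000_000})


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_segment(start, end, seg_mean, sample="S1", chrom="chr1"):
    return CNSegment(sample=sample, chrom=chrom, start=start, end=end, seg_mean=seg_mean)
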
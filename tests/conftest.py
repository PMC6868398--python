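import numpy as np
import pytest

from chipquant.core_intervals import ChromSizes, GenomicInterval


@pytest.fixture
def sizes():
    return ChromSizes({"chrI": 10_000, "chrII": 5_000})


@pytest.fixture
def big_sizes():
    return ChromSizes({"chrI": 1_000_000})


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_interval(rng, chroms=("chrI", "chrII"), max_coord=10_000, max_width=500):
    chrom = chroms[int(rng.integers(0, len(chroms)))]
    start = int(rng.integers(0, max_coord - 1))
    width = int(rng.integers(1, max_width))
    return GenomicInterval(chrom, start, min(start + width, max_coord))
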
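import numpy as np
import pytest

from regulomics.core import ChromSizes, GenomicInterval, RegionSet


@pytest.fixture
def genome():
    return ChromSizes({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_region_set(rng, genome, n, max_len=500, named=True, scored=False):
    """Random intervals over the toy genome, valid by construction."""
    chroms = list(genome)
    intervals = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, genome[chrom] - length))
        intervals.append(
            GenomicInterval(
                chrom,
                start,
                start + length,
                strand=["+", "-", "."][int(rng.integers(0, 3))],
                score=float(rng.integers(0, 100)) if scored else None,
                name=f"iv{i:04d}" if named else None,
            )
        )
    return RegionSet(intervals, name="random", genome=genome)
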
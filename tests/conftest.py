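import numpy as np
import pandas as pd
import pytest

from embryodomains import ChromSizes, GenomicInterval, IntervalSet
from embryodomains.simulate import default_config


@pytest.fixture
def toy_genome():
    return ChromSizes({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def config():
    """The default study conditions at a fixed seed (shared across tests)."""
    return default_config(11)


def random_interval_set(rng, genome, n, max_len=5_000):
    """Random (possibly overlapping) intervals across a toy genome."""
    chroms = list(genome.names())
    rows = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        length = int(rng.integers(1, max_len))
        start = int(rng.integers(0, genome[chrom] - length))
        rows.append((chrom, start, start + length))
    arr = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return IntervalSet.from_arrays(arr["chrom"], arr["start"], arr["end"])


def coverage_mask(s, genome):
    """Per-base boolean-mask oracle for interval-set coverage."""
    masks = {c: np.zeros(genome[c], dtype=bool) for c in genome.names()}
    for iv in s:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks
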
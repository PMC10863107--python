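import numpy as np
import pandas as pd
import pytest

from ltrmap import (
    AlignedReadSet,
    CohortConfig,
    GenomeModel,
    simulate_cohort,
)
from ltrmap.io import READ_COLUMNS


@pytest.fixture
def tiny_genome() -> GenomeModel:
    return GenomeModel(
        chromosomes=(("chr1", 1_200_000), ("chr2", 800_000)),
        env_loci=(("chr1", 600_000, 606_000, "+"),),
    )


@pytest.fixture
def tiny_cfg() -> CohortConfig:
    return CohortConfig(
        n_populations=2,
        individuals_per_population=(2, 2),
        shared_site_pool_size=(4, 4),
        private_site_rate=2,
        target_junction_depth=150,
        background_read_rate=0.0,
        seed=7,
    )


@pytest.fixture
def tiny_cohort(tiny_cfg, tiny_genome):
    return simulate_cohort(tiny_cfg, tiny_genome)


def make_reads(
    intervals, individual="ind1", strand="+", chrom="chr1"
) -> AlignedReadSet:
    """Build a read set from bare (start, end) tuples."""
    rows = [
        (chrom, s, e, f"r{i}", 60, strand)
        for i, (s, e) in enumerate(intervals)
    ]
    return AlignedReadSet(individual, pd.DataFrame(rows, columns=READ_COLUMNS))


def random_reads(
    rng: np.random.Generator,
    n_reads: int,
    chrom_length: int,
    chrom: str = "chr1",
    max_len: int = 500,
    individual: str = "ind1",
) -> AlignedReadSet:
    starts = rng.integers(0, chrom_length - max_len, size=n_reads)
    lengths = rng.integers(1, max_len, size=n_reads)
    rows = [
        (chrom, int(s), int(min(s + l, chrom_length)), f"r{i}", 60, "+")
        for i, (s, l) in enumerate(zip(starts, lengths))
    ]
    return AlignedReadSet(individual, pd.DataFrame(rows, columns=READ_COLUMNS))
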
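import numpy as np
import pytest

from chromaquant import AlignmentRecord, make_toy_genome


@pytest.fixture(scope="session")
def ann20():
    """20-gene toy genome with generous spacing."""
    return make_toy_genome(20, chrom_length=120_000, min_gap=2_500, seed=7)


@pytest.fixture(scope="session")
def ann_tight():
    """Genes packed closely so neighbour masking actually triggers."""
    return make_toy_genome(30, chrom_length=68_000, min_gap=200, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_records(rng, chrom_sizes, n, read_len=50, with_mapq=True):
    """Uniform random alignment records across chromosomes."""
    chroms = sorted(chrom_sizes)
    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, chrom_sizes[chrom] - read_len + 1))
        out.append(
            AlignmentRecord(
                chrom=chrom,
                start=start,
                end=start + read_len,
                strand="+" if rng.random() < 0.5 else "-",
                mapq=int(rng.integers(0, 61)) if with_mapq else 60,
                read_id=f"r{i}",
            )
        )
    return out
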
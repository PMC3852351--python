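import numpy as np
import pytest

from cagetss.genomic_io import ReadStartProfile
from cagetss.peak_calling import GenomicInterval, Peak


def make_profile(chrom_lengths, entries):
    """Build a profile from (chrom, strand, position, count) tuples."""
    profile = ReadStartProfile(chrom_lengths)
    for chrom, strand, pos, count in entries:
        profile.add(chrom, strand, pos, count)
    return profile


def make_peak(chrom, start, end, strand, profile):
    from cagetss.peak_calling import peak_from_interval

    return peak_from_interval(GenomicInterval(chrom, start, end, strand), profile)


@pytest.fixture
def simple_profile():
    """One clean 10-base cluster of 50 reads on chr1:+ in a 2 kb chromosome."""
    entries = [("chr1", "+", 1000 + i, 5) for i in range(10)]
    return make_profile({"chr1": 2000}, entries)


@pytest.fixture
def random_profile():
    """Sparse random background plus two planted clusters, fixed seed."""
    rng = np.random.default_rng(42)
    length = 10_000
    profile = ReadStartProfile({"chr1": length})
    for pos in rng.integers(0, length, size=60):
        profile.add("chr1", "+", int(pos))
    for i in range(8):
        profile.add("chr1", "+", 3000 + i, 8)
        profile.add("chr1", "-", 7000 + i, 6)
    return profile


@pytest.fixture
def small_genome():
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    return {"chr1": seq}


@pytest.fixture(scope="session")
def study():
    """A shared small synthetic study for pipeline-level tests."""
    from cagetss.synthetic_data import simulate_study

    return simulate_study(seed=11, n_cell_lines=3, chrom_length=100_000,
                          n_tss=20, n_non_tss=20)
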
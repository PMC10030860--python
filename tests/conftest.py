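import numpy as np
import pandas as pd
import pytest

from pgii.model import (
    GenomeRecord,
    Group,
    InversionCall,
    NonredundantInversion,
    Species,
)


@pytest.fixture
def small_panel():
    """Two GJ, one XI, one admixed O. sativa plus the two outgroups."""
    return [
        GenomeRecord("ref", Species.SATIVA, Group.GJ, "GJ-temp"),
        GenomeRecord("gj1", Species.SATIVA, Group.GJ, "GJ-temp"),
        GenomeRecord("gj2", Species.SATIVA, Group.GJ, "GJ-trop1"),
        GenomeRecord("xi1", Species.SATIVA, Group.XI, "XI-1A"),
        GenomeRecord("adm1", Species.SATIVA, Group.ADMIXED, "admixed"),
        GenomeRecord("ruf1", Species.RUFIPOGON, Group.OUTGROUP, "outgroup"),
        GenomeRecord("pun1", Species.PUNCTATA, Group.OUTGROUP, "outgroup"),
    ]


def make_call(genome="g1", chrom="Chr01", start=1000, end=2000):
    return InversionCall(
        query_genome=genome, chrom=chrom, ref_start=start, ref_end=end
    )


def random_calls(rng, n, n_genomes=5, n_chroms=2, coord_range=5000, max_len=800):
    """Random call sets dense enough to exercise merging chains."""
    calls = []
    for _ in range(n):
        start = int(rng.integers(1, coord_range))
        length = int(rng.integers(1, max_len))
        calls.append(
            InversionCall(
                query_genome=f"g{rng.integers(1, n_genomes + 1)}",
                chrom=f"Chr{rng.integers(1, n_chroms + 1):02d}",
                ref_start=start,
                ref_end=start + length,
            )
        )
    return calls


def random_index(rng, n, n_chroms=2, coord_range=100_000, max_len=5_000):
    out = []
    for k in range(n):
        start = int(rng.integers(1, coord_range))
        length = int(rng.integers(100, max_len))
        out.append(
            NonredundantInversion(
                inv_id=f"INV{k:04d}",
                chrom=f"Chr{rng.integers(1, n_chroms + 1):02d}",
                ref_start=start,
                ref_end=start + length - 1,
                carriers=frozenset({f"g{rng.integers(1, 6)}"}),
            )
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def presence_matrix(small_panel):
    """6 clusters x 7 genomes with a missing value and the ref column zero."""
    data = pd.DataFrame(
        0.0,
        index=[f"Clu{k}" for k in range(1, 7)],
        columns=[g.genome_id for g in small_panel],
    )
    data.loc["Clu1", ["gj1", "gj2"]] = 1.0
    data.loc["Clu2", ["xi1"]] = 1.0
    data.loc["Clu3", ["ruf1"]] = 1.0
    data.loc["Clu4", ["pun1"]] = 1.0
    data.loc["Clu5", ["gj1", "xi1", "ruf1", "pun1"]] = 1.0
    data.loc["Clu6", ["gj2", "adm1"]] = 1.0
    data.loc["Clu2", "adm1"] = np.nan
    return data
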
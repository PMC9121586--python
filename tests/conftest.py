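import numpy as np
import pandas as pd
import pytest

from bsascan.variants import SITE_COLUMNS


def make_site_table(rows):
    """Site table from tuples in SITE_COLUMNS order."""
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


@pytest.fixture
def rng():
    return np.random.default_rng(20_220_519)


@pytest.fixture
def random_sites(rng):
    """50 random well-formed pooled sites on two chromosomes, sorted."""
    n = 50
    chroms = np.sort(rng.choice(["chr1", "chr2"], size=n))
    pos = np.concatenate([
        np.sort(rng.choice(np.arange(1, 3_000_000), size=(chroms == c).sum(),
                           replace=False))
        for c in ["chr1", "chr2"]])
    ref = rng.choice(list("ACGT"), size=n)
    alt = np.array([{"A": "C", "C": "G", "G": "T", "T": "A"}[r] for r in ref])
    df = make_site_table(list(zip(
        chroms, pos, ref, alt,
        rng.integers(1, 40, n), rng.integers(1, 40, n),
        rng.integers(1, 40, n), rng.integers(1, 40, n),
        rng.integers(0, 60, n).astype(float),
        rng.integers(0, 60, n).astype(float))))
    return df


@pytest.fixture
def small_params():
    """A small, fast F2 design: 3 chromosomes of 8 Mb, QTL mid-chr2."""
    from bsascan.simulate import F2SimParams
    return F2SimParams(
        chrom_lengths={"chr1": 8_000_000, "chr2": 8_000_000,
                       "chr3": 8_000_000},
        snp_spacing=20_000, qtl_chrom="chr2", qtl_pos=4_000_000,
        n_f2=278, pool_size=20, seed=7)
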
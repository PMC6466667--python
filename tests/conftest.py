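import numpy as np
import pytest

from qtloverlap.synthdata import GenotypeSet


def make_genotypes(dosages, pos=None, chrom=None, breed=None, sex=None):
    """GenotypeSet from a raw dosage matrix with simple defaults."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    pos = np.arange(1, m + 1) * 10_000 if pos is None else np.asarray(pos, dtype=np.int64)
    chrom = np.ones(m, dtype=np.int64) if chrom is None else np.asarray(chrom, dtype=np.int64)
    return GenotypeSet(
        dosages,
        chrom,
        pos,
        dosages.mean(axis=0) / 2.0,
        np.array([f"i{k}" for k in range(n)]),
        np.full(n, "A") if breed is None else np.asarray(breed),
        np.full(n, "F") if sex is None else np.asarray(sex),
    )


def random_genotypes(rng, n, m, pos=None, chrom=None, maf_low=0.1, maf_high=0.5):
    """LD-free random dosages at uniform allele frequencies."""
    p = rng.uniform(maf_low, maf_high, size=m)
    d = rng.binomial(2, p, size=(n, m)).astype(float)
    return make_genotypes(d, pos=pos, chrom=chrom)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def demo_genotypes():
    """Small two-breed genotype set with realistic LD, shared across tests."""
    from qtloverlap.synthdata import simulate_genotypes

    return simulate_genotypes(
        (300, 100), 1500, (20_000_000, 20_000_000), fst=0.1, ld_block_scale=100_000, seed=11
    )
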
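import numpy as np
import pytest

from seaselect.types import GenotypeMatrix


def make_gm(genotypes, **kwargs) -> GenotypeMatrix:
    """Build a small GenotypeMatrix with defaulted metadata."""
    genotypes = np.asarray(genotypes, dtype=np.int16)
    n, m = genotypes.shape
    defaults = dict(
        sample_ids=[f"s{i}" for i in range(n)],
        locus_ids=[f"l{j}" for j in range(m)],
        chrom=[f"l{j}" for j in range(m)],
        pos=np.zeros(m, dtype=np.int64),
        ref=np.array(["A"] * m),
        alt=np.array(["C"] * m),
    )
    defaults.update(kwargs)
    return GenotypeMatrix(genotypes=genotypes, **defaults)


def random_gm(rng: np.random.Generator, n: int, m: int, missing_rate=0.0):
    geno = rng.integers(0, 3, size=(n, m)).astype(np.int16)
    if missing_rate:
        geno[rng.random(geno.shape) < missing_rate] = -1
    return make_gm(geno)


@pytest.fixture
def gm_factory():
    return make_gm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
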
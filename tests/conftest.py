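import numpy as np
import pytest

from hapsweep.core import GeneticMap, HaplotypeMatrix


def random_matrix(rng: np.random.Generator, n_hap: int, n_snp: int,
                  span_bp: int = 200_000) -> HaplotypeMatrix:
    """Random polymorphic haplotype matrix with increasing positions."""
    while True:
        alleles = (rng.random((n_hap, n_snp)) < rng.uniform(0.1, 0.9, size=n_snp)).astype(np.int8)
        counts = alleles.sum(axis=0)
        if np.all((counts > 0) & (counts < n_hap)):
            break
    pos = np.sort(rng.choice(np.arange(1, span_bp), size=n_snp, replace=False))
    cm = pos * 1e-6  # 1 cM/Mb
    ids = np.array([f"s{i}" for i in range(n_snp)], dtype=object)
    pops = np.array(["P"] * n_hap, dtype=object)
    return HaplotypeMatrix(alleles, pos, cm, ids, pops)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_matrix():
    """8 haplotypes x 9 SNPs, hand-layout: middle column is the core."""
    alleles = np.array([
        [0, 1, 0, 1, 1, 1, 0, 1, 0],
        [0, 1, 0, 1, 1, 1, 0, 1, 0],
        [1, 0, 1, 0, 1, 1, 1, 0, 1],
        [1, 0, 1, 0, 1, 0, 1, 0, 1],
        [0, 0, 1, 1, 0, 1, 0, 1, 1],
        [0, 0, 1, 1, 0, 1, 0, 1, 0],
        [1, 1, 0, 0, 0, 0, 1, 0, 1],
        [1, 1, 0, 0, 0, 0, 0, 1, 0],
    ], dtype=np.int8)
    pos = np.array([1_000, 3_000, 6_000, 8_000, 10_000, 13_000, 15_000, 18_000, 21_000])
    cm = pos * 1e-6
    ids = np.array([f"s{i}" for i in range(9)], dtype=object)
    pops = np.array(["P"] * 8, dtype=object)
    return HaplotypeMatrix(alleles, pos, cm, ids, pops)


@pytest.fixture
def simple_map():
    return GeneticMap(np.array([0, 100]), np.array([0.0, 1.0]))
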
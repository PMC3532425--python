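import numpy as np
import pytest

from sweepscan import (
    GeneticMap,
    GenotypeMatrix,
    HaplotypePanel,
    PopulationStructure,
    Variant,
)


def make_variants(n, chrom="chr1", spacing=1000, start=1000, ancestral="A"):
    return [
        Variant(f"rs{i}", chrom, start + i * spacing, ("A", "G"), ancestral)
        for i in range(n)
    ]


@pytest.fixture
def tiny_genotypes():
    """3 samples x 2 SNPs with genotypes 0/0, 0/1, 1/1 at both SNPs."""
    variants = make_variants(2)
    codes = np.array([[0, 0], [1, 1], [2, 2]], dtype=np.int8)
    return GenotypeMatrix(["s1", "s2", "s3"], variants, codes)


@pytest.fixture
def small_panel():
    """Deterministic 10-haplotype, 12-SNP phased panel."""
    rng = np.random.default_rng(42)
    haps = rng.integers(0, 2, size=(10, 12)).astype(np.uint8)
    samples = [f"s{i}" for i in range(5) for _ in range(2)]
    return HaplotypePanel(haps, samples, make_variants(12))


@pytest.fixture
def uniform_map():
    return GeneticMap.uniform(1_000_000, 1.0)  # 1 cM/Mb


@pytest.fixture
def two_pop_structure():
    s2p = {f"s{i}": ("popA" if i < 3 else "popB") for i in range(5)}
    return PopulationStructure(s2p, {"popA": "north", "popB": "south"})
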
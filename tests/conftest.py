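import numpy as np
import pytest

from admixscan import SimConfig, simulate_study
from admixscan.panel import GenotypePanel, HaplotypePanel, MarkerMap


@pytest.fixture(scope="session")
def default_study():
    """The default admixture scenario (no injected tract), seed 1."""
    return simulate_study(SimConfig(seed=1))


@pytest.fixture(scope="session")
def sweep_study():
    """Default scenario with the adaptive tract injected at 50 cM."""
    return simulate_study(SimConfig(seed=1, sweep=(50.2, 0.6, 0.9)))


def make_markers(n, chrom="1", spacing_bp=10_000, aa=None):
    pos = (np.arange(n) + 1) * spacing_bp
    return MarkerMap(
        np.full(n, chrom, dtype=object),
        pos,
        pos * 1e-6,
        np.zeros(n, dtype=np.int8) if (np.isscalar(aa) and aa == 0) else aa,
    )


def make_hap_panel(alleles, pops=None, chrom="1", aa=None):
    alleles = np.asarray(alleles, dtype=np.int8)
    n_hap, n_mark = alleles.shape
    assert n_hap % 2 == 0
    n_samples = n_hap // 2
    pops = pops or ["P1"] * n_samples
    samples = [f"s{i+1}" for i in range(n_samples)]
    return HaplotypePanel(alleles, samples, pops, make_markers(n_mark, chrom, aa=aa))


def make_geno_panel(genotypes, pops=None, chrom="1", spacing_bp=10_000):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_mark = genotypes.shape
    pops = pops or ["P1"] * n_samples
    samples = [f"s{i+1}" for i in range(n_samples)]
    return GenotypePanel(
        genotypes, samples, pops, make_markers(n_mark, spacing_bp=spacing_bp)
    )


@pytest.fixture
def tiny_panel():
    """4 haplotypes x 6 markers, two populations, ancestral allele known."""
    alleles = np.array(
        [
            [0, 1, 0, 1, 0, 1],
            [1, 1, 0, 0, 0, 1],
            [0, 0, 1, 1, 1, 0],
            [1, 0, 1, 0, 1, 0],
        ]
    )
    return make_hap_panel(alleles, pops=["P1", "P2"], aa=0)
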
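import numpy as np
import pytest

from hybridcline.ancestry import ParentalReference
from hybridcline.io import GenotypeMatrix
from hybridcline.simulate import make_fixture_dataset


def make_biallelic_reference(p1_w, p1_e, n_gene_copies=200):
    """Reference with given per-locus frequencies of allele 1 in each panel."""
    p1_w = np.atleast_1d(np.asarray(p1_w, dtype=float))
    p1_e = np.atleast_1d(np.asarray(p1_e, dtype=float))
    L = p1_w.size
    freqs = [{0: (1.0 - p1_w[j], 1.0 - p1_e[j]), 1: (p1_w[j], p1_e[j])}
             for j in range(L)]
    return ParentalReference(loci=[f"L{j + 1}" for j in range(L)], freqs=freqs,
                             n_w=np.full(L, n_gene_copies),
                             n_e=np.full(L, n_gene_copies))


def diagnostic_reference(n_loci=40):
    """Fully diagnostic loci: allele 1 fixed in the E panel, absent in W."""
    return make_biallelic_reference([0.0] * n_loci, [1.0] * n_loci)


def genotype_from_dosage(dosage):
    """(L,) E-allele dosages -> (L, 2) allele pairs."""
    d = np.asarray(dosage)
    return np.stack([(d > 1).astype(int), (d > 0).astype(int)], axis=1)


def random_genotype_matrix(rng, n=12, L=5, n_pops=3, max_allele=6,
                           missing_rate=0.1):
    geno = rng.integers(0, max_allele, size=(n, L, 2)).astype(np.int32)
    miss = rng.random((n, L)) < missing_rate
    geno[miss] = -9
    pops = np.array([f"P{rng.integers(1, n_pops + 1)}" for _ in range(n)],
                    dtype=object)
    return GenotypeMatrix(ids=[f"i{k}" for k in range(n)], pops=pops,
                          loci=[f"L{j}" for j in range(L)], geno=geno)


def theta_anova(geno_by_pop):
    """Independent Weir-Cockerham oracle via ANOVA mean squares on allele
    indicator variables (different computational path from the package's
    variance-component formulas)."""
    alleles = np.unique(np.concatenate([g.ravel() for g in geno_by_pop]))
    num = den = 0.0
    r = len(geno_by_pop)
    n_i = np.array([g.shape[0] for g in geno_by_pop], float)
    n_tot = n_i.sum()
    nc = (n_tot - (n_i ** 2).sum() / n_tot) / (r - 1)
    for allele in alleles:
        x = [(g == allele).astype(float) for g in geno_by_pop]
        pbar_w = sum(xi.sum() for xi in x) / (2 * n_tot)
        ssp = sum(2 * ni * (xi.mean() - pbar_w) ** 2 for ni, xi in zip(n_i, x))
        ssg = sum(((xi.sum(axis=1) / 2 - xi.mean()) ** 2 * 2).sum() for xi in x)
        ssw = sum((xi.sum(axis=1) / 2 * (1 - xi.sum(axis=1) / 2) * 2).sum()
                  for xi in x)
        msp = ssp / (r - 1)
        msg = ssg / (n_tot - r)
        msw = ssw / n_tot
        s2a = (msp - msg) / (2 * nc)
        s2b = (msg - msw) / 2
        num += s2a
        den += s2a + s2b + msw
    return num / den


@pytest.fixture(scope="session")
def fixture_dataset():
    return make_fixture_dataset(seed=42)


@pytest.fixture(scope="session")
def diag_ref():
    return diagnostic_reference(40)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
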
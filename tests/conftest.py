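import numpy as np
import pytest

from introgress.genodata import GenotypeTable, Locus, SampleRecord


def make_table(pop_genotypes, locus_names=None, species=None, references=None):
    """Build a GenotypeTable from {pop: [genotype-list, ...]}.

    Each genotype-list is one individual: a list with one (a1, a2) pair or
    None per locus.
    """
    first = next(iter(pop_genotypes.values()))
    n_loci = len(first[0])
    if locus_names is None:
        locus_names = [f"L{j + 1}" for j in range(n_loci)]
    registries = [dict() for _ in range(n_loci)]
    for genos in pop_genotypes.values():
        for g in genos:
            for j, pair in enumerate(g):
                if pair is not None:
                    registries[j].setdefault(pair[0], None)
                    registries[j].setdefault(pair[1], None)
    loci = [Locus(n, tuple(sorted(r))) for n, r in zip(locus_names, registries)]
    samples = []
    for pop, genos in pop_genotypes.items():
        for i, g in enumerate(genos):
            geno = {
                name: (None if pair is None else (pair[0], pair[1]))
                for name, pair in zip(locus_names, g)
            }
            samples.append(
                SampleRecord(
                    id=f"{pop}_{i + 1}",
                    population=pop,
                    species=(species or {}).get(pop, "unknown"),
                    is_reference=pop in (references or ()),
                    genotype=geno,
                )
            )
    return GenotypeTable(loci=loci, samples=samples)


def random_table(rng, n_pops=3, n_per_pop=8, n_loci=4, n_alleles=5, missing_rate=0.1):
    """Random multi-population table for brute-force comparisons."""
    pops = {}
    for p in range(n_pops):
        genos = []
        for _ in range(n_per_pop):
            g = []
            for _ in range(n_loci):
                if rng.random() < missing_rate:
                    g.append(None)
                else:
                    g.append(tuple(int(a) for a in rng.integers(1, n_alleles + 1, 2)))
            genos.append(g)
        pops[f"pop{p + 1}"] = genos
    return make_table(pops)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def het_table():
    """Two populations fixed for alternative alleles at two loci."""
    return make_table(
        {
            "A": [[(1, 1), (3, 3)]] * 6,
            "B": [[(2, 2), (4, 4)]] * 6,
        }
    )
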
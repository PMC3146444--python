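"""Simulation of hybrid and backcross genotypes from two parental pools.

Reproduces the artificial-cross design used to calibrate admixture bins:
from a *graellsii* pool (G) and an *elegans* pool (E), build F1 = G × E,
F2 = F1 × F1, the first *graellsii* backcross GB1 = F1 × G, and the first
to fourth *elegans* backcrosses EB1..EB4 = (previous EB or F1) × E, with
50 offspring per cross by default. Each generated panel serves as the
parental pool for the crosses that depend on it.

Two generator modes:

* ``frequency_draw`` — at every locus each offspring receives one allele
  drawn from each pool's allele-frequency distribution, independently
  across loci (the HYBRID-LAB semantics: Hardy–Weinberg and linkage
  equilibrium within pools);
* ``pedigree`` — one parent individual is drawn uniformly from each pool
  and transmits one uniformly chosen allele per locus, preserving
  within-parent associations (Mendelian segregation; F2 dose spectra get
  their proper ¼/½/¼ shape).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .genodata import GenotypeTable, Locus, SampleRecord, allele_frequencies

__all__ = ["CrossType", "CrossPanel", "simulate_pool_offspring", "generate_cross_panel"]


class CrossType(str, Enum):
    """Cross categories with their expected *I. elegans* ancestry.

    Expected ancestry follows the pedigree recursion
    a(child) = (a(parent A) + a(parent B)) / 2 with a(G)=0, a(E)=1.
    """

    F1 = "F1"
    F2 = "F2"
    GB1 = "GB1"
    EB1 = "EB1"
    EB2 = "EB2"
    EB3 = "EB3"
    EB4 = "EB4"

    @property
    def expected_elegans_ancestry(self) -> float:
        return _EXPECTED_ANCESTRY[self]


_EXPECTED_ANCESTRY = {
    CrossType.F1: 0.5,
    CrossType.F2: 0.5,
    CrossType.GB1: 0.25,
    CrossType.EB1: 0.75,
    CrossType.EB2: 0.875,
    CrossType.EB3: 0.9375,
    CrossType.EB4: 0.96875,
}

#: (cross, parent A, parent B); "G"/"E" are the parental pools.
CROSS_PEDIGREE: list[tuple[CrossType, str, str]] = [
    (CrossType.F1, "G", "E"),
    (CrossType.F2, "F1", "F1"),
    (CrossType.GB1, "F1", "G"),
    (CrossType.EB1, "F1", "E"),
    (CrossType.EB2, "EB1", "E"),
    (CrossType.EB3, "EB2", "E"),
    (CrossType.EB4, "EB3", "E"),
]


def _check_aligned(pool_a: GenotypeTable, pool_b: GenotypeTable) -> None:
    if pool_a.locus_names != pool_b.locus_names:
        raise ValueError(
            "parental pools have mismatched loci: "
            f"{pool_a.locus_names} vs {pool_b.locus_names}"
        )


def _pool_freq_arrays(pool: GenotypeTable) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-locus (allele codes, frequencies) tallied from a pool."""
    gf = allele_frequencies(pool, grouping=lambda s: "pool")
    out = []
    for name, freqs in zip(gf.locus_names, gf.freqs["pool"]):
        if not freqs:
            raise ValueError(f"locus {name!r} has no observed alleles in pool")
        codes = np.array(list(freqs.keys()))
        probs = np.array(list(freqs.values()))
        out.append((codes, probs / probs.sum()))
    return out


def _gamete_frequency(
    pool: GenotypeTable, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n gametes (one allele per locus) drawn from pool allele frequencies."""
    freqs = _pool_freq_arrays(pool)
    gam = np.empty((n, len(freqs)), dtype=np.int64)
    for j, (codes, probs) in enumerate(freqs):
        gam[:, j] = rng.choice(codes, size=n, p=probs)
    return gam


def _gamete_pedigree(pool: GenotypeTable, n: int, rng: np.random.Generator) -> np.ndarray:
    """n gametes by drawing a parent uniformly and segregating its alleles."""
    geno, index = pool.to_arrays()
    if np.any(geno < 0):
        raise ValueError("pedigree mode requires complete genotypes in the pool")
    codes = [np.array(l.alleles) for l in pool.loci]
    parents = rng.integers(0, pool.n_samples, size=n)
    which = rng.integers(0, 2, size=(n, pool.n_loci))
    picked = geno[parents[:, None], np.arange(pool.n_loci)[None, :], which]
    gam = np.empty_like(picked)
    for j in range(pool.n_loci):
        gam[:, j] = codes[j][picked[:, j]]
    return gam


def _offspring_table(
    loci_names: list[str],
    gam_a: np.ndarray,
    gam_b: np.ndarray,
    population: str,
    id_prefix: str,
) -> GenotypeTable:
    n, n_loci = gam_a.shape
    registries = [
        tuple(dict.fromkeys(np.concatenate([gam_a[:, j], gam_b[:, j]]).tolist()))
        for j in range(n_loci)
    ]
    loci = [Locus(name, reg) for name, reg in zip(loci_names, registries)]
    samples = []
    for i in range(n):
        geno = {
            name: (int(gam_a[i, j]), int(gam_b[i, j]))
            for j, name in enumerate(loci_names)
        }
        samples.append(
            SampleRecord(id=f"{id_prefix}_{i + 1}", population=population, genotype=geno)
        )
    return GenotypeTable(loci=loci, samples=samples)


def simulate_pool_offspring(
    pool_a: GenotypeTable,
    pool_b: GenotypeTable,
    n: int,
    mode: str = "frequency_draw",
    seed: int | np.random.SeedSequence | None = None,
    population: str = "offspring",
) -> GenotypeTable:
    """Simulate ``n`` offspring of pool A × pool B.

    Each offspring carries one gamete from each pool at every locus; gamete
    construction follows ``mode`` (see module docstring). Loci must match
    between pools; a pool locus with only missing data is an error.
    """
    _check_aligned(pool_a, pool_b)
    if mode not in ("frequency_draw", "pedigree"):
        raise ValueError("mode must be 'frequency_draw' or 'pedigree'")
    rng = np.random.default_rng(seed)
    draw = _gamete_frequency if mode == "frequency_draw" else _gamete_pedigree
    gam_a = draw(pool_a, n, rng)
    gam_b = draw(pool_b, n, rng)
    return _offspring_table(pool_a.locus_names, gam_a, gam_b, population, population)


@dataclass
class CrossPanel:
    """Simulated genotypes per cross category with their expected ancestry."""

    panels: dict[CrossType, GenotypeTable]
    mode: str
    seed: int
    n_per_cross: int

    def expected_ancestry(self) -> dict[CrossType, float]:
        return {c: c.expected_elegans_ancestry for c in self.panels}

    def to_table(self) -> GenotypeTable:
        """All panels merged into one table, population = cross name.

        Locus registries are unified across panels so the merged table can
        feed the admixture sampler directly.
        """
        names = next(iter(self.panels.values())).locus_names
        registries: list[dict[int, None]] = [dict() for _ in names]
        for panel in self.panels.values():
            for j, l in enumerate(panel.loci):
                for a in l.alleles:
                    registries[j].setdefault(a, None)
        loci = [Locus(n, tuple(reg)) for n, reg in zip(names, registries)]
        samples = []
        for cross, panel in self.panels.items():
            for s in panel.samples:
                samples.append(
                    SampleRecord(
                        id=f"{cross.value}_{s.id}",
                        population=cross.value,
                        genotype=dict(s.genotype),
                    )
                )
        return GenotypeTable(loci=loci, samples=samples)


def generate_cross_panel(
    graellsii_pool: GenotypeTable,
    elegans_pool: GenotypeTable,
    n_per_cross: int = 50,
    mode: str = "frequency_draw",
    seed: int = 0,
) -> CrossPanel:
    """Generate all seven cross categories from the two parental pools.

    Dependent crosses use the previously simulated panel as a parent pool
    (re-tallied as frequencies in ``frequency_draw`` mode, sampled as
    individuals in ``pedigree`` mode). Every cross draws from its own RNG
    substream, so adding or removing a cross never perturbs the others.
    """
    _check_aligned(graellsii_pool, elegans_pool)
    streams = np.random.SeedSequence(seed).spawn(len(CROSS_PEDIGREE))
    pools: dict[str, GenotypeTable] = {"G": graellsii_pool, "E": elegans_pool}
    panels: dict[CrossType, GenotypeTable] = {}
    for (cross, pa, pb), stream in zip(CROSS_PEDIGREE, streams):
        panel = simulate_pool_offspring(
            pools[pa],
            pools[pb],
            n_per_cross,
            mode=mode,
            seed=stream,
            population=cross.value,
        )
        panels[cross] = panel
        pools[cross.value] = panel
    return CrossPanel(panels=panels, mode=mode, seed=seed, n_per_cross=n_per_cross)
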
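"""Synthetic-data generators for every stage of the pipeline.

The field genotypes behind the original survey are not distributed, so the
package ships generators that emulate their structure: two parental taxa
with strong multilocus differentiation at six microsatellite loci, admixed
individuals with known ancestry, artificial-cross panels, mtDNA fragment
panels with prescribed haplotype configurations, and morph-count tables.
Every generator is deterministic under a fixed seed, with independent
substreams per component.

Differentiation between the parental taxa (and among populations within a
taxon) follows the Balding–Nichols model: population allele frequencies are
Dirichlet draws around the ancestral frequencies with concentration
(1 − θ)/θ, so the expected Weir–Cockerham θ between populations matches the
target. Genotypes are Hardy–Weinberg draws from the population frequencies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genodata import (
    GenotypeTable,
    Locus,
    SampleRecord,
    concat_tables,
    write_genepop_file,
    write_structure_file,
)
from .hybrids import CrossPanel, generate_cross_panel
from .mtdna import HaploAlignment

__all__ = [
    "ScenarioSpec",
    "balding_nichols_freqs",
    "simulate_genotypes",
    "simulate_admixed",
    "simulate_mtdna_panel",
    "survey_shape_scenario",
    "ScenarioBundle",
    "MTDNA_CONFIGS",
]

LocusFreqs = list[dict[int, float]]  # per-locus allele code -> frequency


@dataclass(frozen=True)
class ScenarioSpec:
    """Knobs of the full synthetic scenario.

    Defaults emulate the field survey's shape: 442 individuals in 26
    populations (220 European *elegans* + 166 Spanish *elegans* + 56
    *graellsii*), six loci, and a Spanish ancestry mixture of 27% pure,
    58% backcross-like (q ≈ 0.78), 14% F1/F2-like (q ≈ 0.45) plus a single
    *graellsii*-like individual. ``alleles_per_locus`` may be a pair
    (graellsii, elegans) to mimic asymmetric allelic richness between the
    taxa; the default keeps the elegans side richer (10 vs 6), echoing the
    observed imbalance in allele counts.
    """

    n_loci: int = 6
    alleles_per_locus: int | tuple[int, int] = (6, 10)
    target_theta: float = 0.2
    within_theta: float = 0.03
    n_elegans_europe: int = 220
    n_elegans_spain: int = 166
    n_graellsii: int = 56
    n_pops_europe: int = 13
    n_pops_spain: int = 9
    n_pops_graellsii: int = 4
    spanish_mixture: tuple[float, float, float] = (0.27, 0.58, 0.14)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.target_theta < 1.0):
            raise ValueError("target_theta must lie in (0, 1)")
        for n in (self.n_elegans_europe, self.n_elegans_spain, self.n_graellsii):
            if n < 1:
                raise ValueError("group sizes must be >= 1")


def balding_nichols_freqs(
    ancestral_freqs: LocusFreqs,
    theta: float,
    n_pops: int,
    seed: int | np.random.SeedSequence | None = None,
) -> list[LocusFreqs]:
    """Per-population allele frequencies under the Balding–Nichols model.

    Each population's frequencies at each locus are a Dirichlet draw with
    parameters p_anc · (1 − θ)/θ. Ancestral classes with zero frequency
    cannot receive Dirichlet mass and are dropped with a warning.
    """
    if not (0.0 < theta < 1.0):
        raise ValueError("theta must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    conc = (1.0 - theta) / theta
    out: list[LocusFreqs] = [[] for _ in range(n_pops)]
    for l, freqs in enumerate(ancestral_freqs):
        total = sum(freqs.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"ancestral frequencies at locus {l} sum to {total}")
        zero = [a for a, f in freqs.items() if f <= 0.0]
        if zero:
            warnings.warn(
                f"locus {l}: dropping zero-frequency ancestral allele(s) {zero}",
                stacklevel=2,
            )
        codes = [a for a, f in freqs.items() if f > 0.0]
        p = np.array([freqs[a] for a in codes])
        p = p / p.sum()
        draws = rng.dirichlet(p * conc, size=n_pops)
        for i in range(n_pops):
            out[i].append(dict(zip(codes, draws[i].tolist())))
    return out


def _draw_alleles(
    freqs: dict[int, float], size: int, rng: np.random.Generator
) -> np.ndarray:
    codes = np.array(list(freqs.keys()))
    p = np.array(list(freqs.values()))
    return rng.choice(codes, size=size, p=p / p.sum())


def simulate_genotypes(
    freqs: LocusFreqs,
    n: int,
    missing_rate: float = 0.0,
    seed: int | np.random.SeedSequence | None = None,
    population: str = "pop",
    species: str = "unknown",
    region: str = "",
    is_reference: bool = False,
    id_prefix: str | None = None,
    locus_names: list[str] | None = None,
) -> GenotypeTable:
    """Hardy–Weinberg genotypes from per-locus allele frequencies.

    Each genotype is two independent allele draws per locus; whole-locus
    missing entries are inserted independently at ``missing_rate``.
    """
    rng = np.random.default_rng(seed)
    n_loci = len(freqs)
    if locus_names is None:
        locus_names = [f"L{j + 1}" for j in range(n_loci)]
    prefix = id_prefix or population
    draws = [
        _draw_alleles(freqs[j], (n, 2), rng) for j in range(n_loci)
    ]
    miss = (
        rng.random((n, n_loci)) < missing_rate
        if missing_rate > 0
        else np.zeros((n, n_loci), dtype=bool)
    )
    loci = [
        Locus(locus_names[j], tuple(sorted(freqs[j].keys()))) for j in range(n_loci)
    ]
    samples = []
    for i in range(n):
        geno: dict[str, tuple[int, int] | None] = {}
        for j, name in enumerate(locus_names):
            geno[name] = (
                None if miss[i, j] else (int(draws[j][i, 0]), int(draws[j][i, 1]))
            )
        samples.append(
            SampleRecord(
                id=f"{prefix}_{i + 1}",
                population=population,
                species=species,
                region=region,
                is_reference=is_reference,
                genotype=geno,
            )
        )
    return GenotypeTable(loci=loci, samples=samples)


def simulate_admixed(
    freqs_pop1: LocusFreqs,
    freqs_pop2: LocusFreqs,
    true_q: np.ndarray,
    seed: int | np.random.SeedSequence | None = None,
    population: str = "admixed",
    species: str = "unknown",
    region: str = "",
    id_prefix: str | None = None,
    locus_names: list[str] | None = None,
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Admixed genotypes with recorded ground-truth ancestry.

    ``true_q[i]`` is individual i's ancestry fraction from population 2;
    each gene copy's origin is an independent Bernoulli(true_q) draw and
    the allele comes from the origin population's frequencies. Returns the
    genotype table and a truth frame (id, true_q).
    """
    true_q = np.asarray(true_q, dtype=float)
    if np.any((true_q < 0) | (true_q > 1)):
        raise ValueError("true_q entries must lie in [0, 1]")
    if len(freqs_pop1) != len(freqs_pop2):
        raise ValueError("parental frequency lists have different locus counts")
    rng = np.random.default_rng(seed)
    n = len(true_q)
    n_loci = len(freqs_pop1)
    if locus_names is None:
        locus_names = [f"L{j + 1}" for j in range(n_loci)]
    prefix = id_prefix or population

    registries = [
        tuple(sorted(set(freqs_pop1[j]) | set(freqs_pop2[j]))) for j in range(n_loci)
    ]
    loci = [Locus(locus_names[j], registries[j]) for j in range(n_loci)]
    samples = []
    for i in range(n):
        geno = {}
        for j, name in enumerate(locus_names):
            pair = []
            for _ in range(2):
                origin2 = rng.random() < true_q[i]
                src = freqs_pop2[j] if origin2 else freqs_pop1[j]
                pair.append(int(_draw_alleles(src, 1, rng)[0]))
            geno[name] = (pair[0], pair[1])
        samples.append(
            SampleRecord(
                id=f"{prefix}_{i + 1}",
                population=population,
                species=species,
                region=region,
                genotype=geno,
            )
        )
    truth = pd.DataFrame(
        {"id": [s.id for s in samples], "true_q": true_q}
    ).set_index("id")
    return GenotypeTable(loci=loci, samples=samples), truth


# ---------------------------------------------------------------------------
# mtDNA panels
# ---------------------------------------------------------------------------

#: Haplotype configurations of the five mitochondrial fragments:
#: (counts per haplotype, variant site indices per haplotype, length).
MTDNA_CONFIGS: dict[str, tuple[tuple[int, ...], tuple[tuple[int, ...], ...], int]] = {
    "COI": ((13,), ((),), 591),
    "COII": ((9, 3), ((), (100,)), 673),
    "CYTB": ((22, 1, 1), ((), (50,), (200,)), 457),
    "12S": ((65, 1, 1, 1), ((), (40,), (120,), (300,)), 370),
    "ND1": ((7, 1), ((), (250,)), 591),
}


def simulate_mtdna_panel(
    haplotype_counts: tuple[int, ...] | list[int],
    variant_sites: tuple[tuple[int, ...], ...] | list[tuple[int, ...]],
    length: int,
    seed: int | np.random.SeedSequence | None = None,
    allow_overlap: bool = False,
) -> HaploAlignment:
    """Alignment with a prescribed haplotype configuration.

    A random base sequence of ``length`` is generated, haplotype i differs
    from it exactly at ``variant_sites[i]`` (substituted to a different
    base), and the sequences appear in shuffled order. Overlapping site
    sets across haplotypes are rejected unless ``allow_overlap``.
    """
    counts = [int(c) for c in haplotype_counts]
    if len(counts) != len(variant_sites):
        raise ValueError("haplotype_counts and variant_sites differ in length")
    if any(c < 1 for c in counts):
        raise ValueError("haplotype counts must be >= 1")
    flat = [s for sites in variant_sites for s in sites]
    if any(not (0 <= s < length) for s in flat):
        raise ValueError("variant sites must lie within the sequence length")
    if not allow_overlap and len(flat) != len(set(flat)):
        raise ValueError(
            "variant site sets overlap between haplotypes; pass "
            "allow_overlap=True if this is intended"
        )
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    backbone = rng.integers(0, 4, size=length)
    seqs: list[str] = []
    for sites in variant_sites:
        s = backbone.copy()
        for site in sites:
            s[site] = (s[site] + int(rng.integers(1, 4))) % 4
        seqs.append("".join(bases[s]))
    full = [seq for seq, c in zip(seqs, counts) for _ in range(c)]
    order = rng.permutation(len(full))
    return HaploAlignment(
        ids=[f"seq_{i + 1}" for i in range(len(full))],
        sequences=[full[i] for i in order],
    )


# ---------------------------------------------------------------------------
# Full scenario
# ---------------------------------------------------------------------------

@dataclass
class ScenarioBundle:
    """Ready-to-run synthetic dataset emulating the field survey."""

    table: GenotypeTable
    truth: pd.DataFrame  # true elegans-ancestry per individual
    graellsii_freqs: LocusFreqs
    elegans_freqs: LocusFreqs
    cross_panel: CrossPanel
    mtdna: dict[str, HaploAlignment]
    morph_counts: pd.DataFrame
    spec: ScenarioSpec

    def write(self, directory: str | Path) -> dict[str, str]:
        """Write all fixture files (text formats only) plus a JSON manifest.

        Returns the manifest dict; reruns with the same spec/seed produce
        byte-identical files.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_structure_file(self.table, directory / "genotypes.str")
        write_genepop_file(self.table, directory / "genotypes.gen")
        meta = pd.DataFrame(
            {
                "id": [s.id for s in self.table.samples],
                "population": [s.population for s in self.table.samples],
                "species": [s.species for s in self.table.samples],
                "region": [s.region for s in self.table.samples],
                "is_reference": [int(s.is_reference) for s in self.table.samples],
            }
        )
        meta.to_csv(directory / "metadata.csv", index=False)
        self.truth.to_csv(directory / "truth.csv")
        write_structure_file(self.cross_panel.to_table(), directory / "crosses.str")
        for gene, aln in self.mtdna.items():
            lines = []
            for sid, seq in zip(aln.ids, aln.sequences):
                lines.append(f">{sid}")
                lines.append(seq)
            (directory / f"{gene}.fasta").write_text("\n".join(lines) + "\n")
        self.morph_counts.to_csv(directory / "morph_counts.csv", index=False)
        manifest = {
            "seed": self.spec.seed,
            "n_individuals": self.table.n_samples,
            "n_populations": len(self.table.populations()),
            "n_loci": self.table.n_loci,
            "total_alleles": self.table.total_allele_count(),
            "cross_mode": self.cross_panel.mode,
            "mtdna_genes": sorted(self.mtdna),
            "files": sorted(p.name for p in directory.iterdir() if p.suffix != ".json"),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return manifest


def _split_sizes(total: int, n_groups: int) -> list[int]:
    base, extra = divmod(total, n_groups)
    return [base + (i < extra) for i in range(n_groups)]


def _spanish_true_q(
    n: int, mixture: tuple[float, float, float], rng: np.random.Generator
) -> np.ndarray:
    """Ancestry mixture for Spanish individuals: pure, backcross-like,
    F1/F2-like, and one graellsii-like individual (cosmetic shape only)."""
    n_pure = int(round(mixture[0] * n))
    n_back = int(round(mixture[1] * n))
    n_mixed = int(round(mixture[2] * n))
    n_rest = n - n_pure - n_back - n_mixed
    q = np.concatenate(
        [
            np.ones(n_pure),
            np.clip(rng.normal(0.78, 0.05, size=n_back), 0.69, 0.89),
            np.clip(rng.normal(0.45, 0.08, size=n_mixed), 0.22, 0.66),
            np.full(max(n_rest, 0), 0.03),
        ]
    )[:n]
    rng.shuffle(q)
    return q


def survey_shape_scenario(
    seed: int = 0, spec: ScenarioSpec | None = None
) -> ScenarioBundle:
    """Generate the full synthetic scenario.

    Builds ancestral allele frequencies, splits them into the two taxa with
    Balding–Nichols differentiation at ``target_theta``, adds mild
    within-taxon population structure, samples reference individuals for
    every non-Spanish population, draws Spanish individuals with a known
    ancestry mixture, simulates the seven artificial-cross panels, the five
    mtDNA fragment panels and a morph-count table.
    """
    if spec is None:
        spec = ScenarioSpec(seed=seed)
    elif spec.seed != seed:
        spec = ScenarioSpec(**{**spec.__dict__, "seed": seed})
    root = np.random.SeedSequence(spec.seed)
    (
        ss_anc,
        ss_species,
        ss_pops,
        ss_geno,
        ss_admix,
        ss_cross,
        ss_mtdna,
        ss_morph,
    ) = root.spawn(8)
    rng_anc = np.random.default_rng(ss_anc)

    if isinstance(spec.alleles_per_locus, int):
        n_alleles_g = n_alleles_e = spec.alleles_per_locus
    else:
        n_alleles_g, n_alleles_e = spec.alleles_per_locus
    n_total_alleles = max(n_alleles_g, n_alleles_e)

    # microsatellite-style allele codes (even fragment sizes per locus)
    ancestral: LocusFreqs = []
    for l in range(spec.n_loci):
        codes = [100 + 10 * l + 2 * a for a in range(n_total_alleles)]
        p = rng_anc.dirichlet(np.full(n_total_alleles, 1.0))
        # guard against near-zero classes so both taxa can inherit them
        p = (p + 0.02) / (p + 0.02).sum()
        ancestral.append(dict(zip(codes, p.tolist())))

    graellsii_f, elegans_f = balding_nichols_freqs(
        ancestral, spec.target_theta, 2, seed=ss_species
    )

    def restrict(freqs: LocusFreqs, n_keep: int) -> LocusFreqs:
        # ascertainment-style asymmetry: keep the n_keep most frequent
        # alleles per locus and renormalise
        out = []
        for f in freqs:
            top = dict(sorted(f.items(), key=lambda kv: -kv[1])[:n_keep])
            s = sum(top.values())
            out.append({a: v / s for a, v in top.items()})
        return out

    graellsii_f = restrict(graellsii_f, n_alleles_g)
    elegans_f = restrict(elegans_f, n_alleles_e)

    rng_pops = np.random.default_rng(ss_pops)
    pop_seeds = ss_geno.spawn(
        spec.n_pops_graellsii + spec.n_pops_europe + spec.n_pops_spain
    )
    seed_iter = iter(pop_seeds)

    g_pop_freqs = balding_nichols_freqs(
        graellsii_f, spec.within_theta, spec.n_pops_graellsii, seed=rng_pops.integers(2**31)
    )
    e_pop_freqs = balding_nichols_freqs(
        elegans_f, spec.within_theta, spec.n_pops_europe, seed=rng_pops.integers(2**31)
    )

    locus_names = [f"L{j + 1}" for j in range(spec.n_loci)]
    tables: list[GenotypeTable] = []

    g_sizes = _split_sizes(spec.n_graellsii, spec.n_pops_graellsii)
    for i, (sz, fr) in enumerate(zip(g_sizes, g_pop_freqs)):
        tables.append(
            simulate_genotypes(
                fr,
                sz,
                missing_rate=spec.missing_rate,
                seed=next(seed_iter),
                population=f"graellsii_{i + 1}",
                species="graellsii",
                region="Iberia-Africa",
                is_reference=True,
                locus_names=locus_names,
            )
        )
    e_sizes = _split_sizes(spec.n_elegans_europe, spec.n_pops_europe)
    for i, (sz, fr) in enumerate(zip(e_sizes, e_pop_freqs)):
        tables.append(
            simulate_genotypes(
                fr,
                sz,
                missing_rate=spec.missing_rate,
                seed=next(seed_iter),
                population=f"europe_{i + 1}",
                species="elegans",
                region="Europe-not-Spain",
                is_reference=True,
                locus_names=locus_names,
            )
        )

    rng_admix = np.random.default_rng(ss_admix)
    s_sizes = _split_sizes(spec.n_elegans_spain, spec.n_pops_spain)
    truth_frames = []
    for i, sz in enumerate(s_sizes):
        q = _spanish_true_q(sz, spec.spanish_mixture, rng_admix)
        tab, truth = simulate_admixed(
            graellsii_f,
            elegans_f,
            q,
            seed=next(seed_iter),
            population=f"spain_{i + 1}",
            species="elegans",
            region="Spain",
            locus_names=locus_names,
        )
        tables.append(tab)
        truth_frames.append(truth)

    table = concat_tables(tables)

    truth = pd.concat(truth_frames)
    ref_truth = pd.DataFrame(
        {
            "true_q": [
                1.0 if s.species == "elegans" else 0.0
                for s in table.samples
                if s.is_reference
            ]
        },
        index=pd.Index(
            [s.id for s in table.samples if s.is_reference], name="id"
        ),
    )
    truth = pd.concat([ref_truth, truth])

    # pool over all graellsii / non-Spanish elegans samples for crosses
    g_all = table.subset(lambda s: s.species == "graellsii")
    e_all = table.subset(lambda s: s.region == "Europe-not-Spain")
    cross_panel = generate_cross_panel(
        g_all,
        e_all,
        n_per_cross=50,
        mode="frequency_draw",
        seed=int(np.random.default_rng(ss_cross).integers(2**31)),
    )

    mt_seeds = ss_mtdna.spawn(len(MTDNA_CONFIGS))
    mtdna = {
        gene: simulate_mtdna_panel(counts, sites, length, seed=s)
        for (gene, (counts, sites, length)), s in zip(MTDNA_CONFIGS.items(), mt_seeds)
    }

    rng_morph = np.random.default_rng(ss_morph)
    morph_rows = []
    for pop, species, probs in [
        ("graellsii_1", "graellsii", (0.12, 0.75, 0.13)),
        ("graellsii_2", "graellsii", (0.10, 0.80, 0.10)),
        ("spain_1", "elegans", (0.45, 0.35, 0.20)),
        ("spain_2", "elegans", (0.15, 0.30, 0.55)),
        ("spain_3", "elegans", (0.70, 0.25, 0.05)),
    ]:
        n_females = int(rng_morph.integers(20, 80))
        counts = rng_morph.multinomial(n_females, probs)
        morph_rows.append(
            {
                "population": pop,
                "species": species,
                "date": "2007",
                "N": n_females,
                "count_androchrome": int(counts[0]),
                "count_infuscans": int(counts[1]),
                "count_obsoleta": int(counts[2]),
            }
        )
    morph_counts = pd.DataFrame(morph_rows)

    return ScenarioBundle(
        table=table,
        truth=truth,
        graellsii_freqs=graellsii_f,
        elegans_freqs=elegans_f,
        cross_panel=cross_panel,
        mtdna=mtdna,
        morph_counts=morph_counts,
        spec=spec,
    )
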
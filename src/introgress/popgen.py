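"""Per-group diversity and differentiation statistics for codominant loci.

Implements the FSTAT-style battery used to characterise hybridizing
populations: observed and (unbiased, Nei) expected heterozygosity, allele
counts, rarefied allelic richness, the Weir–Cockerham (1984)
variance-components estimator of FST (θ) with a whole-genotype permutation
test, and the female colour-morph frequency table.

Group-level diversity values are unweighted means over loci; multilocus θ is
the ratio of summed variance components (ratio of sums, not mean of ratios).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genodata import GenotypeTable, GroupingSpec, allele_frequencies

__all__ = [
    "observed_heterozygosity",
    "expected_heterozygosity",
    "allele_counts",
    "allelic_richness",
    "diversity_table",
    "FstResult",
    "wc_fst",
    "fst_permutation_test",
    "morph_frequency_table",
]


def _group_index(table: GenotypeTable, grouping: GroupingSpec) -> dict[str, list[int]]:
    labels = table.group_labels(grouping)
    out: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        out.setdefault(lab, []).append(i)
    return out


def _finish_frame(values: dict[str, list[float]], locus_names: list[str]) -> pd.DataFrame:
    """Assemble a per-group frame with a 'mean' column (unweighted over loci).

    Loci with no data in a group hold NaN and are excluded from the mean.
    """
    df = pd.DataFrame.from_dict(values, orient="index", columns=locus_names)
    df.index.name = "group"
    df["mean"] = df[locus_names].mean(axis=1, skipna=True)
    return df


def observed_heterozygosity(
    table: GenotypeTable, grouping: GroupingSpec = "population"
) -> pd.DataFrame:
    """Ho per (group, locus): fraction of non-missing genotypes that are
    heterozygous. All-missing cells are NaN, never zero."""
    idx = _group_index(table, grouping)
    values: dict[str, list[float]] = {}
    for g, members in idx.items():
        row = []
        for l in table.loci:
            n = het = 0
            for i in members:
                pair = table.samples[i].genotype[l.name]
                if pair is None:
                    continue
                n += 1
                het += pair[0] != pair[1]
            row.append(het / n if n else np.nan)
        values[g] = row
    return _finish_frame(values, table.locus_names)


def expected_heterozygosity(
    table: GenotypeTable, grouping: GroupingSpec = "population"
) -> pd.DataFrame:
    """Nei's unbiased gene diversity per (group, locus).

    He = (2n / (2n − 1)) (1 − Σ p_k²) with n the number of non-missing
    diploid genotypes; cells with fewer than one genotype are NaN.
    """
    gf = allele_frequencies(table, grouping)
    values: dict[str, list[float]] = {}
    for g in gf.groups:
        row = []
        for freqs, copies in zip(gf.freqs[g], gf.gene_counts[g]):
            if copies < 2:
                row.append(np.nan)
                continue
            sum_p2 = sum(p * p for p in freqs.values())
            row.append(copies / (copies - 1) * (1.0 - sum_p2))
        values[g] = row
    return _finish_frame(values, gf.locus_names)


def allele_counts(
    table: GenotypeTable, grouping: GroupingSpec = "population"
) -> pd.DataFrame:
    """Number of distinct alleles observed per (group, locus); 'mean' column
    replaced by the group total over loci."""
    gf = allele_frequencies(table, grouping)
    values = {g: [float(len(f)) for f in gf.freqs[g]] for g in gf.groups}
    df = pd.DataFrame.from_dict(values, orient="index", columns=gf.locus_names)
    df.index.name = "group"
    df["total"] = df.sum(axis=1)
    return df


def _rarefied_richness(allele_copies: np.ndarray, g: int) -> float:
    """Expected allele count in a random subsample of ``g`` gene copies.

    Σ_i [1 − C(N−N_i, g) / C(N, g)] evaluated on the log scale; alleles with
    fewer than g complementary copies contribute exactly 1.
    """
    N = int(allele_copies.sum())
    if g > N:
        raise ValueError(f"rarefaction size g={g} exceeds gene count N={N}")

    def log_comb(n: int, k: int) -> float:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    total = 0.0
    for n_i in allele_copies:
        rest = N - int(n_i)
        if rest < g:
            total += 1.0
        else:
            total += 1.0 - float(np.exp(log_comb(rest, g) - log_comb(N, g)))
    return total


def allelic_richness(
    table: GenotypeTable,
    grouping: GroupingSpec = "population",
    g: int | None = None,
) -> pd.DataFrame:
    """Rarefied allelic richness per (group, locus) at ``g`` gene copies.

    By default ``g`` is the smallest non-missing gene count over all
    (group, locus) cells — the FSTAT convention, which makes richness
    comparable across the groups in the table.
    """
    gf = allele_frequencies(table, grouping)
    if g is None:
        all_counts = [c for grp in gf.groups for c in gf.gene_counts[grp]]
        g = min(all_counts)
    if g < 2:
        raise ValueError(f"rarefaction size must be >= 2, got {g}")
    values: dict[str, list[float]] = {}
    for grp in gf.groups:
        row = []
        for freqs, copies in zip(gf.freqs[grp], gf.gene_counts[grp]):
            if copies < g:
                row.append(np.nan)
                continue
            counts = np.array([round(p * copies) for p in freqs.values()], dtype=np.int64)
            row.append(_rarefied_richness(counts, g))
        values[grp] = row
    df = _finish_frame(values, gf.locus_names)
    df.attrs["rarefaction_g"] = g
    return df


def diversity_table(
    table: GenotypeTable,
    grouping: GroupingSpec = "population",
    rarefaction_g: int | None = None,
) -> pd.DataFrame:
    """Summary frame with one row per group: N, Ho, He, Alleles, Richness.

    The shape mirrors the usual per-population diversity report for
    microsatellite surveys.
    """
    idx = _group_index(table, grouping)
    ho = observed_heterozygosity(table, grouping)
    he = expected_heterozygosity(table, grouping)
    ac = allele_counts(table, grouping)
    ar = allelic_richness(table, grouping, rarefaction_g)
    out = pd.DataFrame(
        {
            "N": {g: len(m) for g, m in idx.items()},
            "Ho": ho["mean"],
            "He": he["mean"],
            "Alleles": ac["total"].astype(int),
            "Richness": ar["mean"],
        }
    )
    out.index.name = "group"
    out.attrs["rarefaction_g"] = ar.attrs["rarefaction_g"]
    return out


# ---------------------------------------------------------------------------
# Weir–Cockerham FST
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    """Multilocus Weir–Cockerham θ with optional permutation p-value."""

    theta: float
    per_locus_theta: pd.Series
    p_value: float | None = None
    n_permutations: int = 0


def _wc_components(
    geno: np.ndarray, group_ids: np.ndarray, n_groups: int, n_alleles: list[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Summed variance components (a, a+b+c) per locus.

    ``geno``: (N, L, 2) allele indices with −1 missing. Follows the
    Weir & Cockerham (1984) estimator: per locus and allele, among-group
    (a), among-individual-within-group (b) and within-individual (c)
    components; loci monomorphic over all groups contribute nothing.
    """
    n_loci = geno.shape[1]
    num = np.zeros(n_loci)
    den = np.zeros(n_loci)
    for l in range(n_loci):
        gl = geno[:, l, :]
        valid = gl[:, 0] >= 0
        if valid.sum() == 0:
            continue
        gids = group_ids[valid]
        gl = gl[valid]
        # per-group sample sizes (diploid individuals with data)
        n_i = np.bincount(gids, minlength=n_groups).astype(float)
        pops = np.flatnonzero(n_i > 0)
        r = len(pops)
        if r < 2:
            continue
        n_i = n_i[pops]
        nbar = n_i.mean()
        nsum = n_i.sum()
        nc = (nsum - (n_i**2).sum() / nsum) / (r - 1)
        remap = -np.ones(n_groups, dtype=np.int64)
        remap[pops] = np.arange(r)
        gids_r = remap[gids]
        for a in range(n_alleles[l]):
            dose = (gl == a).sum(axis=1).astype(float)  # 0, 1, 2 copies
            het = ((gl[:, 0] == a) ^ (gl[:, 1] == a)).astype(float)
            p_i = np.bincount(gids_r, weights=dose, minlength=r) / (2 * n_i)
            h_i = np.bincount(gids_r, weights=het, minlength=r) / n_i
            pbar = (n_i * p_i).sum() / nsum
            if pbar <= 0.0 or pbar >= 1.0:
                continue
            s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n_i * h_i).sum() / nsum
            a_comp = (nbar / nc) * (
                s2
                - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b_comp = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c_comp = hbar / 2
            num[l] += a_comp
            den[l] += a_comp + b_comp + c_comp
    return num, den


def wc_fst(table: GenotypeTable, grouping: GroupingSpec = "population") -> FstResult:
    """Weir–Cockerham (1984) θ over the groups defined by ``grouping``.

    The multilocus value is the ratio of summed variance components over all
    alleles and loci. Requires at least two groups with data.
    """
    labels = table.group_labels(grouping)
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("wc_fst requires at least two groups")
    gid = np.array([uniq.index(lab) for lab in labels])
    geno, _ = table.to_arrays()
    n_alleles = [l.n_alleles for l in table.loci]
    num, den = _wc_components(geno, gid, len(uniq), n_alleles)
    per_locus = pd.Series(
        np.where(den != 0, num / np.where(den == 0, 1, den), np.nan),
        index=table.locus_names,
        name="theta",
    )
    total_den = den.sum()
    theta = float(num.sum() / total_den) if total_den != 0 else float("nan")
    return FstResult(theta=theta, per_locus_theta=per_locus)


def fst_permutation_test(
    table: GenotypeTable,
    grouping: GroupingSpec = "population",
    n_perm: int = 999,
    seed: int | None = None,
) -> FstResult:
    """Permutation test of θ, permuting whole multilocus genotypes.

    Individuals (not gene copies) are shuffled among groups, preserving
    within-individual associations; p = (1 + #{θ* ≥ θ̂}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = table.group_labels(grouping)
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("permutation test requires at least two groups")
    gid = np.array([uniq.index(lab) for lab in labels])
    geno, _ = table.to_arrays()
    n_alleles = [l.n_alleles for l in table.loci]

    def theta_of(ids: np.ndarray) -> float:
        num, den = _wc_components(geno, ids, len(uniq), n_alleles)
        d = den.sum()
        return float(num.sum() / d) if d != 0 else float("nan")

    obs = theta_of(gid)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(gid)
        if theta_of(perm) >= obs:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    num, den = _wc_components(geno, gid, len(uniq), n_alleles)
    per_locus = pd.Series(
        np.where(den != 0, num / np.where(den == 0, 1, den), np.nan),
        index=table.locus_names,
        name="theta",
    )
    return FstResult(theta=obs, per_locus_theta=per_locus, p_value=p, n_permutations=n_perm)


# ---------------------------------------------------------------------------
# Colour-morph frequency table
# ---------------------------------------------------------------------------

MORPH_COUNT_COLS = ["count_androchrome", "count_infuscans", "count_obsoleta"]
MORPH_PCT_COLS = ["pct_androchrome", "pct_infuscans", "pct_obsoleta"]


def morph_frequency_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Female colour-morph percentages from raw counts.

    Input rows carry (population, species, date, N) and the three morph
    counts (androchrome, infuscans, infuscans-obsoleta). Percentages are
    100·count/N rounded to one decimal. Counts must sum to N; rows with
    N = 0 are flagged and get no percentages.
    """
    for col in ["population", "N", *MORPH_COUNT_COLS]:
        if col not in counts.columns:
            raise ValueError(f"missing column {col!r}")
    if (counts[MORPH_COUNT_COLS] < 0).any().any():
        raise ValueError("morph counts must be non-negative")
    out = counts.copy()
    sums = out[MORPH_COUNT_COLS].sum(axis=1)
    bad = sums != out["N"]
    nonzero_bad = bad & (out["N"] > 0)
    if nonzero_bad.any():
        rows = out.index[nonzero_bad].tolist()
        raise ValueError(f"morph counts do not sum to N in rows {rows}")
    out["flagged_empty"] = out["N"] == 0
    for cc, pc in zip(MORPH_COUNT_COLS, MORPH_PCT_COLS):
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * out[cc] / out["N"]
        out[pc] = pct.round(1)
        out.loc[out["flagged_empty"], pc] = np.nan
    return out
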
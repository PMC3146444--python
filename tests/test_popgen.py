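"""Diversity statistics, Weir–Cockerham θ and the morph-frequency table."""

import itertools

import numpy as np
import pandas as pd
import pytest

from introgress.genodata import allele_frequencies
from introgress.popgen import (
    allelic_richness,
    diversity_table,
    expected_heterozygosity,
    fst_permutation_test,
    morph_frequency_table,
    observed_heterozygosity,
    wc_fst,
)

from conftest import make_table, random_table


class TestHeterozygosity:
    def test_all_homozygous_and_all_heterozygous(self):
        t = make_table({"A": [[(1, 1)], [(2, 2)]], "B": [[(1, 2)], [(1, 2)]]})
        ho = observed_heterozygosity(t)
        assert ho.loc["A", "L1"] == 0.0
        assert ho.loc["B", "L1"] == 1.0

    def test_all_missing_locus_is_absent_not_zero(self):
        t = make_table({"A": [[(1, 2), None], [(1, 1), None]]})
        ho = observed_heterozygosity(t)
        assert np.isnan(ho.loc["A", "L2"])

    def test_ho_matches_direct_count(self, rng):
        t = random_table(rng)
        ho = observed_heterozygosity(t)
        for g in t.populations():
            for locus in t.loci:
                pairs = [
                    s.genotype[locus.name]
                    for s in t.samples
                    if s.population == g and s.genotype[locus.name] is not None
                ]
                if pairs:
                    expected = sum(a != b for a, b in pairs) / len(pairs)
                    assert ho.loc[g, locus.name] == pytest.approx(expected)

    def test_he_monomorphic_is_zero(self):
        t = make_table({"A": [[(5, 5)], [(5, 5)]]})
        assert expected_heterozygosity(t).loc["A", "L1"] == 0.0

    def test_he_two_heterozygotes_unbiased_value(self):
        # two individuals both 1/2: p = 0.5, He = (4/3) * 0.5 = 2/3
        t = make_table({"A": [[(1, 2)], [(1, 2)]]})
        assert expected_heterozygosity(t).loc["A", "L1"] == pytest.approx(2 / 3)

    def test_he_matches_formula_from_tallies(self, rng):
        t = random_table(rng)
        he = expected_heterozygosity(t)
        gf = allele_frequencies(t)
        for g in t.populations():
            for j, name in enumerate(t.locus_names):
                c = gf.gene_counts[g][j]
                if c < 2:
                    continue
                sp2 = sum(p**2 for p in gf.freqs[g][j].values())
                assert he.loc[g, name] == pytest.approx(c / (c - 1) * (1 - sp2))

    def test_he_invariant_to_allele_relabeling(self, rng):
        t = random_table(rng, missing_rate=0.0)
        relabeled = make_table(
            {
                pop: [
                    [
                        (s.genotype[n][0] + 100, s.genotype[n][1] + 100)
                        for n in t.locus_names
                    ]
                    for s in t.samples
                    if s.population == pop
                ]
                for pop in t.populations()
            }
        )
        a = expected_heterozygosity(t)
        b = expected_heterozygosity(relabeled)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())


class TestAllelicRichness:
    def test_monomorphic_is_one(self):
        t = make_table({"A": [[(1, 1)]] * 5, "B": [[(1, 1)]] * 5})
        ar = allelic_richness(t, g=4)
        assert ar.loc["A", "L1"] == pytest.approx(1.0)

    def test_full_size_equals_allele_count(self):
        t = make_table({"A": [[(1, 2)], [(3, 3)], [(1, 1)]]})
        ar = allelic_richness(t, g=6)
        assert ar.loc["A", "L1"] == pytest.approx(3.0)

    def test_matches_exhaustive_subsample_enumeration(self):
        # N = 6 gene copies, allele counts {3, 2, 1}, g = 4
        t = make_table({"A": [[(1, 1)], [(1, 2)], [(2, 3)]]})
        copies = [1, 1, 1, 2, 2, 3]
        expected = np.mean(
            [len(set(sub)) for sub in itertools.combinations(copies, 4)]
        )
        ar = allelic_richness(t, g=4)
        assert ar.loc["A", "L1"] == pytest.approx(expected)

    def test_monotone_in_g(self, rng):
        t = random_table(rng, n_pops=1, n_per_pop=10, missing_rate=0.0)
        values = [
            allelic_richness(t, g=g).loc["pop1"].drop("mean").to_numpy()
            for g in range(2, 20)
        ]
        for lo, hi in zip(values, values[1:]):
            assert np.all(hi >= lo - 1e-12)

    def test_small_g_rejected(self):
        t = make_table({"A": [[(1, 2)]] * 3})
        with pytest.raises(ValueError, match=">= 2"):
            allelic_richness(t, g=1)


def _wc_theta_reference(t, grouping="population"):
    """Independent transcription of the Weir–Cockerham (1984) estimator.

    Plain-Python loops over loci and alleles; ratio of summed components.
    """
    pops = t.populations()
    num = den = 0.0
    for locus in t.loci:
        per_pop = {
            p: [s.genotype[locus.name] for s in t.samples
                if s.population == p and s.genotype[locus.name] is not None]
            for p in pops
        }
        per_pop = {p: g for p, g in per_pop.items() if g}
        r = len(per_pop)
        if r < 2:
            continue
        n_i = {p: len(g) for p, g in per_pop.items()}
        nbar = sum(n_i.values()) / r
        nsum = sum(n_i.values())
        nc = (nsum - sum(v * v for v in n_i.values()) / nsum) / (r - 1)
        alleles = set(a for g in per_pop.values() for pair in g for a in pair)
        for allele in alleles:
            p_i = {
                p: sum((pair[0] == allele) + (pair[1] == allele) for pair in g)
                / (2 * n_i[p])
                for p, g in per_pop.items()
            }
            h_i = {
                p: sum((pair[0] == allele) != (pair[1] == allele) for pair in g)
                / n_i[p]
                for p, g in per_pop.items()
            }
            pbar = sum(n_i[p] * p_i[p] for p in per_pop) / nsum
            if pbar <= 0 or pbar >= 1:
                continue
            s2 = sum(n_i[p] * (p_i[p] - pbar) ** 2 for p in per_pop) / ((r - 1) * nbar)
            hbar = sum(n_i[p] * h_i[p] for p in per_pop) / nsum
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            num += a
            den += a + b + c
    return num / den


class TestWcFst:
    def test_fixed_difference_theta_is_one(self, het_table):
        assert wc_fst(het_table).theta == pytest.approx(1.0)

    def test_duplicated_population_theta_near_zero(self):
        genos = [[(1, 2)], [(1, 1)], [(2, 2)], [(1, 2)], [(2, 2)]]
        t = make_table({"A": genos, "B": genos})
        assert wc_fst(t).theta <= 0.05

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_transcription(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, n_pops=3, n_per_pop=10, n_loci=3)
        assert wc_fst(t).theta == pytest.approx(_wc_theta_reference(t))

    def test_single_group_rejected(self):
        t = make_table({"A": [[(1, 2)]] * 4})
        with pytest.raises(ValueError, match="two groups"):
            wc_fst(t)


class TestFstPermutation:
    def test_fixed_difference_minimum_p(self, het_table):
        res = fst_permutation_test(het_table, n_perm=99, seed=0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_p_on_grid_and_deterministic(self, rng):
        t = random_table(rng, n_pops=2, n_per_pop=10, missing_rate=0.0)
        r1 = fst_permutation_test(t, n_perm=49, seed=7)
        r2 = fst_permutation_test(t, n_perm=49, seed=7)
        assert r1.p_value == r2.p_value
        grid = [(1 + k) / 50 for k in range(50)]
        assert min(abs(r1.p_value - g) for g in grid) < 1e-12

    def test_type_i_error_calibration(self):
        """Splitting one panmictic population at random: p should be ~uniform.

        Checks the rejection rate at alpha = 0.05 over replicate datasets
        against its binomial sampling band.
        """
        n_rep, alpha, n_perm = 200, 0.05, 39
        rejections = 0
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            genos = [
                [tuple(int(a) for a in rng.integers(1, 5, 2)) for _ in range(2)]
                for _ in range(16)
            ]
            t = make_table({"A": genos[:8], "B": genos[8:]})
            res = fst_permutation_test(t, n_perm=n_perm, seed=rep)
            rejections += res.p_value <= alpha
        rate = rejections / n_rep
        # binomial 3-sigma band around 0.05 for n=200
        assert abs(rate - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / n_rep)


def test_diversity_table_shape(rng):
    t = random_table(rng, missing_rate=0.0)
    dt = diversity_table(t)
    assert list(dt.columns) == ["N", "Ho", "He", "Alleles", "Richness"]
    assert (dt["Richness"] <= dt["Alleles"] + 1e-9).all()
    assert dt["N"].sum() == t.n_samples


class TestMorphTable:
    def test_simple_percentages(self):
        df = pd.DataFrame(
            [{"population": "p", "species": "elegans", "date": "2007", "N": 4,
              "count_androchrome": 1, "count_infuscans": 1, "count_obsoleta": 2}]
        )
        out = morph_frequency_table(df)
        assert out.loc[0, ["pct_androchrome", "pct_infuscans", "pct_obsoleta"]].tolist() == [
            25.0, 25.0, 50.0,
        ]

    def test_single_morph_population(self):
        # the Saïdia-like pattern: one morph absent entirely
        df = pd.DataFrame(
            [{"population": "p", "species": "graellsii", "date": "2009", "N": 29,
              "count_androchrome": 29, "count_infuscans": 0, "count_obsoleta": 0}]
        )
        out = morph_frequency_table(df)
        assert out.loc[0, "pct_androchrome"] == 100.0
        assert out.loc[0, "pct_infuscans"] == 0.0

    def test_rounding_matches_published_style(self):
        # counts consistent with a 69.7 / 27.3 / 3.0 row at N=33
        df = pd.DataFrame(
            [{"population": "Alfaro", "species": "elegans", "date": "2007", "N": 33,
              "count_androchrome": 23, "count_infuscans": 9, "count_obsoleta": 1}]
        )
        out = morph_frequency_table(df)
        assert out.loc[0, "pct_androchrome"] == 69.7
        assert out.loc[0, "pct_infuscans"] == 27.3
        assert out.loc[0, "pct_obsoleta"] == 3.0

    def test_zero_n_flagged(self):
        df = pd.DataFrame(
            [{"population": "p", "species": "elegans", "date": "", "N": 0,
              "count_androchrome": 0, "count_infuscans": 0, "count_obsoleta": 0}]
        )
        out = morph_frequency_table(df)
        assert out.loc[0, "flagged_empty"]
        assert np.isnan(out.loc[0, "pct_androchrome"])

    def test_inconsistent_counts_rejected(self):
        df = pd.DataFrame(
            [{"population": "p", "species": "elegans", "date": "", "N": 5,
              "count_androchrome": 1, "count_infuscans": 1, "count_obsoleta": 1}]
        )
        with pytest.raises(ValueError, match="sum to N"):
            morph_frequency_table(df)
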
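"""Parsing, writing and allele-frequency tallies for genotype tables."""

import numpy as np
import pytest

from introgress.genodata import (
    GenotypeParseError,
    allele_frequencies,
    attach_metadata,
    concat_tables,
    read_genepop_file,
    read_structure_file,
    write_genepop_file,
    write_structure_file,
)
from introgress.synthetic import survey_shape_scenario

from conftest import make_table, random_table


class TestStructureDialect:
    def test_two_row_dialect_smallest_file(self, tmp_path):
        text = "LOC1\nind1 popA 0 120\nind1 popA 0 122\nind2 popA 0 120\nind2 popA 0 120\n"
        path = tmp_path / "g.str"
        path.write_text(text)
        t = read_structure_file(path, one_row_per_individual=False)
        assert t.n_samples == 2
        assert t.n_loci == 1
        assert t.loci[0].alleles == (120, 122)
        assert t.samples[0].genotype["LOC1"] == (120, 122)

    def test_one_row_dialect_and_popflag(self, tmp_path):
        path = tmp_path / "g.str"
        path.write_text("LOC1 LOC2\nind1 popA 1 120 122 200 200\nind2 popB 0 120 120 200 202\n")
        t = read_structure_file(path)
        assert t.samples[0].is_reference and not t.samples[1].is_reference
        assert t.populations() == ["popA", "popB"]

    def test_missing_genotype_roundtrip(self, tmp_path):
        path = tmp_path / "g.str"
        path.write_text("LOC1 LOC2\nind1 popA 0 -9 -9 200 202\n")
        t = read_structure_file(path)
        assert t.samples[0].genotype["LOC1"] is None
        assert t.samples[0].genotype["LOC2"] == (200, 202)

    def test_half_missing_rejected(self, tmp_path):
        path = tmp_path / "g.str"
        path.write_text("LOC1\nind1 popA 0 -9 120\n")
        with pytest.raises(GenotypeParseError, match="half-missing"):
            read_structure_file(path)

    def test_ragged_row_names_line(self, tmp_path):
        path = tmp_path / "g.str"
        path.write_text("LOC1\nind1 popA 0 120 122\nind2 popA 0 120\n")
        with pytest.raises(GenotypeParseError, match="line 3"):
            read_structure_file(path)

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "g.str"
        path.write_text("LOC1\nind1 popA 0 120 122\nind1 popA 0 120 120\n")
        with pytest.raises(GenotypeParseError, match="duplicate"):
            read_structure_file(path)

    @pytest.mark.parametrize("one_row", [True, False])
    def test_write_read_roundtrip(self, tmp_path, rng, one_row):
        t = random_table(rng)
        path = tmp_path / "g.str"
        write_structure_file(t, path, one_row_per_individual=one_row)
        back = read_structure_file(path, one_row_per_individual=one_row)
        assert back.locus_names == t.locus_names
        for a, b in zip(t.samples, back.samples):
            assert a.id == b.id and a.population == b.population
            assert a.genotype == b.genotype

    def test_survey_shape_fixture_parses(self, tmp_path):
        """A dataset with the survey's shape: 442 individuals, 26 pops, 6 loci."""
        bundle = survey_shape_scenario(seed=1)
        bundle.write(tmp_path)
        t = read_structure_file(tmp_path / "genotypes.str")
        assert t.n_samples == 442
        assert len(t.populations()) == 26
        assert t.n_loci == 6


class TestGenepopDialect:
    def test_single_individual_homozygotes(self, tmp_path):
        path = tmp_path / "g.gen"
        path.write_text("title\nL1\nL2\nPop\nid1 , 0101 0202\n")
        t = read_genepop_file(path)
        assert t.n_loci == 2
        assert t.samples[0].genotype["L1"] == (1, 1)
        assert t.samples[0].genotype["L2"] == (2, 2)

    def test_two_pop_blocks(self, tmp_path):
        path = tmp_path / "g.gen"
        path.write_text(
            "title\nL1\nPop\na1 , 0102\na2 , 0101\nPop\nb1 , 0202\n"
        )
        t = read_genepop_file(path)
        pops = t.populations()
        assert len(pops) == 2
        sizes = {p: sum(s.population == p for s in t.samples) for p in pops}
        assert sorted(sizes.values()) == [1, 2]

    def test_missing_and_mixed_encoding(self, tmp_path):
        path = tmp_path / "g.gen"
        path.write_text("t\nL1\nPop\na1 , 000000\na2 , 001002\n")
        t = read_genepop_file(path)
        assert t.samples[0].genotype["L1"] is None
        bad = tmp_path / "bad.gen"
        bad.write_text("t\nL1\nPop\na1 , 0101\na2 , 001002\n")
        with pytest.raises(GenotypeParseError, match="mixes"):
            read_genepop_file(bad)

    def test_roundtrip_preserves_genotypes(self, tmp_path, rng):
        t = random_table(rng, n_alleles=9)
        path = tmp_path / "g.gen"
        write_genepop_file(t, path)
        back = read_genepop_file(path)
        assert back.locus_names == t.locus_names
        for a, b in zip(t.samples, back.samples):
            assert a.genotype == b.genotype


def test_attach_metadata(tmp_path):
    t = make_table({"A": [[(1, 2)]], "B": [[(2, 2)]]})
    csv = tmp_path / "meta.csv"
    csv.write_text(
        "id,population,species,region,is_reference\n"
        "A_1,A,graellsii,Iberia-Africa,1\nB_1,B,elegans,Spain,0\n"
    )
    attach_metadata(t, csv)
    assert t.samples[0].species == "graellsii"
    assert t.samples[0].is_reference
    assert t.samples[1].region == "Spain"


class TestAlleleFrequencies:
    def test_heterozygote_and_fixed(self):
        t = make_table({"A": [[(1, 2)]], "B": [[(3, 3)], [(3, 3)]]})
        gf = allele_frequencies(t)
        assert gf.freqs["A"][0] == {1: 0.5, 2: 0.5}
        assert gf.freqs["B"][0] == {3: 1.0}
        assert gf.gene_counts["B"][0] == 4

    def test_unknown_group_errors(self):
        t = make_table({"A": [[(1, 2)]]})
        with pytest.raises(ValueError, match="unknown group"):
            allele_frequencies(t, groups=["Z"])

    def test_matches_brute_force_tally(self, rng):
        t = random_table(rng)
        gf = allele_frequencies(t)
        for g in gf.groups:
            for j, locus in enumerate(t.loci):
                tally = {}
                total = 0
                for s in t.samples:
                    if s.population != g:
                        continue
                    pair = s.genotype[locus.name]
                    if pair is None:
                        continue
                    for a in pair:
                        tally[a] = tally.get(a, 0) + 1
                        total += 1
                # gene counts equal 2 × non-missing genotypes
                assert gf.gene_counts[g][j] == total
                for a, c in tally.items():
                    assert gf.freqs[g][j][a] == pytest.approx(c / total)
                if total:
                    assert sum(gf.freqs[g][j].values()) == pytest.approx(1.0)


def test_concat_tables_unifies_registries():
    t1 = make_table({"A": [[(1, 1)]]})
    t2 = make_table({"B": [[(2, 2)]]})
    merged = concat_tables([t1, t2])
    assert merged.loci[0].alleles == (1, 2)
    assert merged.n_samples == 2
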
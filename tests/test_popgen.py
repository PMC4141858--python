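"""Frequencies, heterozygosity, Weir-Cockerham f and theta, permutation tests."""

import numpy as np
import pytest

from clonepart import popgen
from clonepart.genotype_io import panel_from_records


def build_panel(pop_genotypes, n_loci=1):
    """pop_genotypes: {pop: [genotype, ...]} with genotype = list of pairs."""
    records = []
    k = 0
    for pop, genos in pop_genotypes.items():
        for g in genos:
            k += 1
            records.append((f"i{k}", pop, "", "", g))
    loci = [f"L{j}" for j in range(n_loci)]
    return panel_from_records(loci, records)


def hw_panel(rng, pop, n, freqs_by_locus, alleles_by_locus):
    genos = []
    for _ in range(n):
        g = [
            tuple(sorted(rng.choice(a, 2, p=f)))
            for f, a in zip(freqs_by_locus, alleles_by_locus)
        ]
        genos.append(g)
    return genos


class TestAlleleFrequencies:
    def test_counts_by_hand(self):
        panel = build_panel({"P": [[(189, 203)], [(189, 189)]]})
        fr = popgen.allele_frequencies(panel, "sample")
        assert fr.freqs("P", "L0") == {189: 0.75, 203: 0.25}
        assert fr.gene_copies.iloc[0]["n_gene_copies"] == 4

    def test_monomorphic_population(self):
        panel = build_panel({"P": [[(100, 100)], [(100, 100)]]})
        fr = popgen.allele_frequencies(panel, "sample")
        assert fr.freqs("P", "L0") == {100: 1.0}

    def test_table1_lineage_a_fixed_locus(self, table1_panel):
        fr = popgen.allele_frequencies(table1_panel, "mll")
        assert fr.freqs("A", "CIR-Ms-G08") == {229: 1.0}

    def test_unmapped_individual_errors(self):
        panel = build_panel({"P": [[(1, 2)]]})
        with pytest.raises(KeyError):
            popgen.allele_frequencies(panel, {"other": "P"})


class TestHeterozygosity:
    def test_all_heterozygous(self):
        panel = build_panel({"P": [[(1, 2)]] * 5})
        het = popgen.heterozygosity(panel, "sample")
        assert het["Ho"].iloc[0] == 1.0

    def test_monomorphic_locus_zero(self):
        panel = build_panel({"P": [[(4, 4)]] * 5})
        het = popgen.heterozygosity(panel, "sample")
        assert het["Ho"].iloc[0] == 0.0
        assert het["He"].iloc[0] == 0.0

    def test_unbiased_he_by_hand(self):
        panel = build_panel({"P": [[(189, 203)], [(189, 189)]]})
        het = popgen.heterozygosity(panel, "sample")
        assert het["Ho"].iloc[0] == pytest.approx(0.5)
        assert het["He"].iloc[0] == pytest.approx((4 / 3) * (1 - 0.625))

    def test_single_individual_flagged_nan(self):
        panel = build_panel({"P": [[(1, 2)]]})
        het = popgen.heterozygosity(panel, "sample")
        assert np.isnan(het["He"].iloc[0])


class TestFis:
    def test_maximal_excess_is_minus_one(self):
        panel = build_panel({"P": [[(1, 2)]] * 10})
        _, multi = popgen.fis_estimate(panel, "sample")
        assert multi["P"] == pytest.approx(-1.0)

    def test_near_zero_under_hardy_weinberg(self):
        rng = np.random.default_rng(17)
        genos = hw_panel(
            rng, "P", 500,
            [[0.4, 0.3, 0.2, 0.1]] * 5,
            [[100, 102, 104, 106]] * 5,
        )
        panel = build_panel({"P": genos}, n_loci=5)
        _, multi = popgen.fis_estimate(panel, "sample")
        assert abs(multi["P"]) < 0.05

    def test_monomorphic_locus_excluded(self):
        panel = build_panel(
            {"P": [[(1, 2), (9, 9)], [(1, 2), (9, 9)]]}, n_loci=2
        )
        per_locus, multi = popgen.fis_estimate(panel, "sample")
        assert np.isnan(
            per_locus.loc[per_locus["locus"] == "L1", "f_is"].iloc[0]
        )
        assert multi["P"] == pytest.approx(-1.0)

    def test_table1_lineage_c_monomorphic_locus(self, table1_panel):
        per_locus, _ = popgen.fis_estimate(table1_panel, "mll")
        row = per_locus[
            (per_locus["population"] == "C")
            & (per_locus["locus"] == "CIR-Ms-B03")
        ]
        assert np.isnan(row["f_is"].iloc[0])

    def test_table1_lineages_show_heterozygote_excess(self, table1_panel):
        het = popgen.heterozygosity(table1_panel, "mll")
        _, multi = popgen.fis_estimate(table1_panel, "mll")
        for pop, f in multi.items():
            assert f < 0
        variable = het[(het["He"] > 0) & (het["Ho"] > 0)]
        assert (variable["Ho"] >= variable["He"] - 0.25).all()


class TestPairwiseFst:
    def test_fixed_difference_gives_one(self):
        panel = build_panel(
            {
                "PA": [[(100, 100), (110, 110)]] * 10,
                "PB": [[(102, 102), (112, 112)]] * 10,
            },
            n_loci=2,
        )
        assert popgen.pairwise_fst(panel, "PA", "PB", "sample") == pytest.approx(1.0)

    def test_hand_computed_variance_components(self):
        # pop1: 10 AA + 10 aa; pop2: 10 Aa + 10 aa -> theta = 7/76 by hand
        panel = build_panel(
            {
                "P1": [[(100, 100)]] * 10 + [[(102, 102)]] * 10,
                "P2": [[(100, 102)]] * 10 + [[(102, 102)]] * 10,
            }
        )
        theta = popgen.pairwise_fst(panel, "P1", "P2", "sample")
        assert theta == pytest.approx(7 / 76, abs=1e-12)

    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(23)
        f = [[0.4, 0.3, 0.2, 0.1]] * 5
        a = [[100, 102, 104, 106]] * 5
        panel = build_panel(
            {
                "A": hw_panel(rng, "A", 200, f, a),
                "B": hw_panel(rng, "B", 200, f, a),
            },
            n_loci=5,
        )
        assert abs(popgen.pairwise_fst(panel, "A", "B", "sample")) < 0.02

    def test_no_usable_locus_errors(self):
        panel = build_panel({"A": [[(5, 5)]] * 3, "B": [[(5, 5)]] * 3})
        with pytest.raises(ValueError, match="polymorphic"):
            popgen.pairwise_fst(panel, "A", "B", "sample")


class TestHWETest:
    def test_heterozygote_excess_detected(self):
        panel = build_panel({"P": [[(1, 2)]] * 20})
        p = popgen.hwe_test(
            panel, "P", "L0", "sample", "excess", n_perm=10_000, seed=1
        )
        assert p <= 0.01

    def test_monomorphic_returns_one(self):
        panel = build_panel({"P": [[(3, 3)]] * 5})
        with pytest.warns(UserWarning, match="monomorphic"):
            p = popgen.hwe_test(panel, "P", "L0", "sample", n_perm=100, seed=0)
        assert p == 1.0

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(5)
        genos = hw_panel(rng, "P", 40, [[0.5, 0.5]], [[100, 102]])
        panel = build_panel({"P": genos})
        p1 = popgen.hwe_test(panel, "P", "L0", "sample", n_perm=500, seed=42)
        p2 = popgen.hwe_test(panel, "P", "L0", "sample", n_perm=500, seed=42)
        assert p1 == p2
        assert 0 < p1 <= 1

    def test_global_excess_on_clonal_population(self):
        panel = build_panel(
            {"P": [[(1, 2), (3, 4), (5, 5)]] * 15}, n_loci=3
        )
        p = popgen.hwe_test_global(
            panel, "P", "sample", "excess", n_perm=10_000, seed=2
        )
        assert p <= 0.01

    def test_deficit_side_is_complementary(self):
        panel = build_panel({"P": [[(1, 2)]] * 20})
        p_def = popgen.hwe_test(
            panel, "P", "L0", "sample", "deficit", n_perm=1000, seed=3
        )
        assert p_def == 1.0


class TestGTest:
    def test_identical_counts_give_zero(self):
        genos = [[(1, 2)]] * 10
        panel = build_panel({"A": genos, "B": list(genos)})
        res = popgen.g_test_differentiation(panel, "sample", n_perm=200, seed=0)
        g_row = res[res["locus"] == "global"].iloc[0]
        assert g_row["G"] == pytest.approx(0.0)
        assert g_row["p"] == 1.0

    def test_fixed_difference_hand_g(self):
        panel = build_panel({"A": [[(1, 1)]] * 10, "B": [[(2, 2)]] * 10})
        res = popgen.g_test_differentiation(panel, "sample", n_perm=999, seed=1)
        # 2x2 table of 20/0 vs 0/20: G = 2 * 40 * ln 2
        expected = 2 * (20 * np.log(2) + 20 * np.log(2))
        g_row = res[res["locus"] == "L0"].iloc[0]
        assert g_row["G"] == pytest.approx(expected)
        assert g_row["p"] <= 0.001 + 1e-9

    def test_single_population_rejected(self):
        panel = build_panel({"A": [[(1, 2)]] * 4})
        with pytest.raises(ValueError, match="two populations"):
            popgen.g_test_differentiation(panel, "sample")

    def test_global_sums_per_locus(self):
        rng = np.random.default_rng(9)
        f = [[0.7, 0.3], [0.2, 0.8]]
        a = [[100, 102], [200, 202]]
        panel = build_panel(
            {
                "A": hw_panel(rng, "A", 30, f, a),
                "B": hw_panel(rng, "B", 30, [[0.3, 0.7], [0.8, 0.2]], a),
            },
            n_loci=2,
        )
        res = popgen.g_test_differentiation(panel, "sample", n_perm=200, seed=4)
        per_locus = res[res["locus"] != "global"]["G"].sum()
        assert res[res["locus"] == "global"]["G"].iloc[0] == pytest.approx(
            per_locus
        )
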
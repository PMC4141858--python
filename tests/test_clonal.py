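"""MLG collapse, allelic distances, threshold, MLL assignment, p_sex, richness."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone as sk_clone
from sklearn.metrics import adjusted_rand_score

from clonepart import clonal
from clonepart.clonal import (
    LineageDelimiter,
    ThresholdNotFound,
    assign_mll,
    clonal_richness,
    collapse_mlg,
    detect_threshold,
    distance_histogram,
    distance_matrix,
    p_gen,
    p_sex,
    pairwise_allele_distance,
    psex_for_mlls,
    representative_per_sample,
    round_robin_frequencies,
)
from clonepart.genotype_io import panel_from_records

from conftest import brute_force_allele_distance


class TestCollapseMLG:
    def test_table1_has_36_mlgs(self, table1_mlgs):
        assert table1_mlgs.n_mlg == 36
        assert int(table1_mlgs.counts.sum()) == 36

    def test_identical_records_collapse_to_one(self):
        panel = panel_from_records(
            ["L1", "L2"],
            [(f"i{k}", "s1", "", "", [(1, 2), (3, 3)]) for k in range(5)],
        )
        mlgs = collapse_mlg(panel)
        assert mlgs.n_mlg == 1
        assert int(mlgs.counts.iloc[0]) == 5

    def test_counts_match_construction(self):
        genotypes = [[(1, 1)], [(1, 2)], [(2, 2)], [(2, 3)]]
        records = []
        for k in range(20):
            records.append((f"i{k}", f"s{k % 3}", "", "", genotypes[k % 4]))
        mlgs = collapse_mlg(panel_from_records(["L1"], records))
        assert mlgs.n_mlg == 4
        assert sorted(mlgs.counts) == [5, 5, 5, 5]

    def test_all_missing_individual_excluded_with_warning(self):
        panel = panel_from_records(
            ["L1"], [("a", "s", "", "", [(0, 0)]), ("b", "s", "", "", [(3, 4)])]
        )
        with pytest.warns(UserWarning, match="no scored locus"):
            mlgs = collapse_mlg(panel)
        assert mlgs.n_mlg == 1
        assert "a" not in mlgs.membership

    def test_ids_independent_of_row_order(self, table1_panel):
        shuffled = table1_panel.subset(np.random.default_rng(0).permutation(36))
        a = collapse_mlg(table1_panel)
        b = collapse_mlg(shuffled)
        assert a.mlg_ids == b.mlg_ids
        assert np.array_equal(a.representatives, b.representatives)


class TestRepresentativePerSample:
    def test_copies_within_sample_reduce_to_one(self):
        panel = panel_from_records(
            ["L1"], [(f"i{k}", "s1", "", "", [(1, 2)]) for k in range(5)]
        )
        assert representative_per_sample(panel).n_individuals == 1

    def test_same_mlg_kept_once_per_sample(self):
        panel = panel_from_records(
            ["L1"],
            [
                ("a", "s1", "", "", [(1, 2)]),
                ("b", "s2", "", "", [(1, 2)]),
                ("c", "s2", "", "", [(1, 2)]),
            ],
        )
        kept = representative_per_sample(panel)
        assert kept.individuals == ["a", "b"]

    def test_count_equals_distinct_mlgs_per_sample(self):
        rng = np.random.default_rng(11)
        genotypes = [[(1, 1)], [(1, 2)], [(2, 2)]]
        records = [
            (f"i{k}", f"s{rng.integers(6)}", "", "", genotypes[rng.integers(3)])
            for k in range(60)
        ]
        panel = panel_from_records(["L1"], records)
        kept = representative_per_sample(panel)
        expected = (
            pd.DataFrame(
                {
                    "sample": panel.meta["sample"],
                    "g": [panel.genotype_key(i) for i in range(60)],
                }
            )
            .drop_duplicates()
            .shape[0]
        )
        assert kept.n_individuals == expected

    def test_idempotent(self, table1_panel):
        once = representative_per_sample(table1_panel)
        twice = representative_per_sample(once)
        assert twice.equals(once)


class TestAllelicDistance:
    def test_published_neighbours(self, table1_panel):
        g = {
            name: table1_panel.alleles[table1_panel.individuals.index(name)]
            for name in ("Ms1", "Ms2", "Ms5", "Ms30")
        }
        assert pairwise_allele_distance(g["Ms1"], g["Ms2"]) == 1
        assert pairwise_allele_distance(g["Ms5"], g["Ms30"]) == 2
        assert pairwise_allele_distance(g["Ms5"], g["Ms5"]) == 0

    def test_shared_allele_counts_one_not_two(self):
        # 206/210 vs 204/206 share one allele -> one difference
        a = np.array([[206, 210]])
        b = np.array([[204, 206]])
        assert pairwise_allele_distance(a, b) == 1

    def test_agrees_with_brute_force_on_all_pairs(self, table1_panel):
        n = table1_panel.n_individuals
        for i, j in itertools.combinations(range(n), 2):
            gi, gj = table1_panel.alleles[i], table1_panel.alleles[j]
            assert pairwise_allele_distance(gi, gj) == brute_force_allele_distance(
                gi, gj
            )

    def test_missing_loci_skipped_and_rescaled(self):
        a = np.array([[1, 2], [3, 4], [0, 0], [7, 8]])
        b = np.array([[1, 2], [5, 6], [9, 9], [7, 7]])
        # comparable loci: 0 (d 0), 1 (d 2), 3 (d 1) -> 3 over 3 of 4 loci
        assert pairwise_allele_distance(a, b) == 4
        assert pairwise_allele_distance(a, b, rescale_missing=False) == 3

    def test_locus_set_mismatch_errors(self):
        with pytest.raises(ValueError, match="locus"):
            pairwise_allele_distance(np.zeros((2, 2)), np.zeros((3, 2)))


class TestDistanceMatrix:
    def test_table1_matrix_shape_and_minimum(self, table1_distances):
        assert table1_distances.d.shape == (36, 36)
        off = table1_distances.d[np.triu_indices(36, 1)]
        assert off.min() == 1

    def test_lineage_block_structure(self, table1_distances, table1_mlgs,
                                     table1_printed_mll):
        label = [
            table1_printed_mll[table1_mlgs.members[m][0]]
            for m in table1_distances.ids
        ]
        d = table1_distances.d
        for i, j in itertools.combinations(range(36), 2):
            if label[i] == label[j]:
                assert 1 <= d[i, j] <= 4
            else:
                assert d[i, j] >= 5

    def test_histogram_totals(self, table1_distances):
        hist = distance_histogram(table1_distances)
        assert int(hist.sum()) == 36 * 35 // 2

    def test_histogram_equals_brute_tally(self, table1_distances):
        hist = distance_histogram(table1_distances)
        iu = np.triu_indices(36, 1)
        tally = pd.Series(table1_distances.d[iu]).value_counts()
        for d, c in tally.items():
            assert hist[d] == c

    def test_metric_axioms_on_all_triples(self, table1_panel):
        n = table1_panel.n_individuals
        d = np.zeros((n, n), dtype=int)
        for i, j in itertools.combinations(range(n), 2):
            d[i, j] = d[j, i] = pairwise_allele_distance(
                table1_panel.alleles[i], table1_panel.alleles[j]
            )
        assert (d >= 0).all() and (np.diag(d) == 0).all()
        for i, j, k in itertools.combinations(range(n), 3):
            assert d[i, j] <= d[i, k] + d[k, j]


class TestThreshold:
    def test_table1_first_minimum_at_five(self, table1_distances):
        assert detect_threshold(distance_histogram(table1_distances)) == 5

    def test_documented_scan_example(self):
        hist = pd.Series({1: 10, 2: 3, 3: 0, 4: 1, 5: 8, 6: 20})
        assert detect_threshold(hist) == 3

    def test_strictly_increasing_histogram_errors(self):
        with pytest.raises(ThresholdNotFound):
            detect_threshold(pd.Series({1: 1, 2: 2, 3: 5, 4: 9}))

    def test_exhaustive_scan_oracle_on_random_histograms(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            top = int(rng.integers(3, 12))
            counts = rng.integers(0, 10, size=top + 1)
            counts[0] = 0
            hist = pd.Series(counts[1:], index=range(1, top + 1))
            expected = None
            for d in range(2, top):
                if counts[d] < counts[d - 1] and counts[d] <= counts[d + 1]:
                    expected = d
                    break
            if expected is None:
                with pytest.raises(ThresholdNotFound):
                    detect_threshold(hist)
            else:
                assert detect_threshold(hist) == expected


class TestAssignMLL:
    def test_table1_reproduces_published_partition(
        self, table1_distances, table1_mlgs, table1_printed_mll
    ):
        part = assign_mll(table1_distances, 5)
        assert part.n_mll == 5
        ours = [part.membership[m] for m in table1_distances.ids]
        printed = [
            table1_printed_mll[table1_mlgs.members[m][0]]
            for m in table1_distances.ids
        ]
        assert adjusted_rand_score(printed, ours) == 1.0
        sizes = sorted(len(part.members_of(k)) for k in range(5))
        assert sizes == [2, 2, 4, 8, 20]

    def test_threshold_one_isolates_every_mlg(self, table1_distances):
        part = assign_mll(table1_distances, 1)
        assert part.n_mll == 36

    def test_single_linkage_chains(self):
        from clonepart.clonal import DistanceMatrix

        d = np.array([[0, 3, 6], [3, 0, 3], [6, 3, 0]])
        part = assign_mll(DistanceMatrix(["A", "B", "C"], d), 4)
        assert part.n_mll == 1

    def test_labels_deterministic_by_first_member(self, table1_distances):
        part = assign_mll(table1_distances, 5)
        first_seen = []
        for m, l in zip(part.mlg_ids, part.labels):
            if l not in first_seen:
                first_seen.append(l)
        assert first_seen == sorted(first_seen)


class TestLineageDelimiter:
    def test_fit_on_allele_array_matches_functions(self, table1_panel, table1_mlgs):
        est = LineageDelimiter()
        est.fit(table1_mlgs.representatives)
        assert est.threshold_ == 5
        assert est.n_lineages_ == 5
        ref = assign_mll(distance_matrix(table1_mlgs), 5)
        assert adjusted_rand_score(ref.labels, est.labels_) == 1.0

    def test_precomputed_metric(self, table1_distances):
        est = LineageDelimiter(metric="precomputed", threshold=5)
        labels = est.fit_predict(table1_distances.d)
        assert len(set(labels)) == 5

    def test_sklearn_protocol(self):
        est = LineageDelimiter(threshold=3)
        params = est.get_params()
        assert params["threshold"] == 3
        cloned = sk_clone(est)
        assert cloned.get_params() == params


class TestPgenPsex:
    def test_single_locus_heterozygote_under_hw(self):
        freqs = [{1: 0.5, 2: 0.5}]
        assert p_gen(np.array([[1, 2]]), freqs) == pytest.approx(0.5)

    def test_fixed_homozygote_probability_one(self):
        assert p_gen(np.array([[7, 7]]), [{7: 1.0}]) == pytest.approx(1.0)

    def test_product_over_loci(self):
        freqs = [{1: 0.5, 2: 0.5}, {3: 0.5, 4: 0.5}]
        g = np.array([[1, 2], [3, 4]])
        assert p_gen(g, freqs) == pytest.approx(0.25)

    def test_fis_correction_directions(self):
        freqs = [{1: 0.5, 2: 0.5}]
        het = np.array([[1, 2]])
        hom = np.array([[1, 1]])
        assert p_gen(het, freqs, f_is=-0.5) > p_gen(het, freqs, f_is=0.0)
        assert p_gen(hom, freqs, f_is=0.5) > p_gen(hom, freqs, f_is=0.0)

    def test_unknown_allele_errors(self):
        with pytest.raises(ValueError, match="absent"):
            p_gen(np.array([[9, 9]]), [{1: 1.0}])

    @pytest.mark.parametrize(
        "pg,n,N,expected",
        [(0.5, 2, 2, 0.25), (0.0, 2, 10, 0.0), (1.0, 2, 10, 1.0)],
    )
    def test_psex_binomial_tail(self, pg, n, N, expected):
        assert p_sex(pg, n, N) == pytest.approx(expected)

    def test_psex_requires_repeats(self):
        with pytest.raises(ValueError):
            p_sex(0.5, 1, 10)

    def test_psex_monotone_in_pgen_and_N(self):
        grid = np.linspace(0.01, 0.99, 15)
        for n_copies in (2, 4):
            vals = [p_sex(pg, n_copies, 20) for pg in grid]
            assert all(b >= a for a, b in zip(vals, vals[1:]))
            vals_n = [p_sex(0.1, n_copies, N) for N in range(n_copies, 60)]
            assert all(b >= a for a, b in zip(vals_n, vals_n[1:]))

    def test_round_robin_counts_each_background_once(self):
        # MLGs sharing the same background at the other loci collapse to one
        # unit at the focal locus; alleles thereby lost keep one pseudo-copy.
        reps = np.array([[[1, 1], [3, 4]], [[2, 2], [3, 4]]])
        freqs = round_robin_frequencies(reps)
        assert freqs[0] == {1: 2 / 3, 2: 1 / 3}
        # distinct backgrounds are each counted
        reps2 = np.array(
            [[[1, 1], [3, 4]], [[1, 1], [5, 6]], [[2, 2], [7, 8]]]
        )
        freqs2 = round_robin_frequencies(reps2)
        assert freqs2[0] == {1: 4 / 6, 2: 2 / 6}

    def test_table1_lineages_all_below_cutoff(self, table1_mlgs, table1_distances):
        part = assign_mll(table1_distances, 5)
        report = psex_for_mlls(table1_mlgs, part)
        assert (report["p_sex"] < 0.01).all()
        assert report["n_copies"].sum() == 36


class TestClonalRichness:
    def test_published_values(self):
        assert clonal_richness(36, 98).rounded() == 0.361
        assert clonal_richness(5, 98).rounded() == 0.041

    def test_bounds(self):
        assert clonal_richness(1, 50).R == 0.0
        assert clonal_richness(50, 50).R == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clonal_richness(3, 1)
        with pytest.raises(ValueError):
            clonal_richness(0, 10)
        with pytest.raises(ValueError):
            clonal_richness(11, 10)
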
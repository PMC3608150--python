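"""Abundance bins, saturation, ratio bins, overlaps, clustering, enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from dgetags.profile_summaries import (
    abundance_distribution,
    cluster_degs,
    expression_overlaps,
    ratio_distribution,
    saturation_curve,
    term_enrichment,
)
from dgetags.tag_processing import TagLibrary
from dgetags.workflow import deg_log2_matrix


def clean_lib(counts, lib_id="x"):
    return TagLibrary(lib_id, counts, stage="clean")


T = ["CATG" + b * 17 for b in "ACGT"]


class TestAbundance:
    def test_hand_binning(self):
        lib = clean_lib({T[0]: 3, T[1]: 4, T[2]: 150})
        dist = abundance_distribution(lib)
        frame = dist.to_frame().set_index("bin")
        assert frame.loc["[2,5]", "distinct"] == 2
        assert frame.loc["[2,5]", "copies"] == 7
        assert frame.loc[">100", "distinct"] == 1
        assert frame.loc[">100", "copies"] == 150

    def test_empty_library_all_zero(self):
        dist = abundance_distribution(clean_lib({}))
        assert sum(dist.distinct) == 0 and sum(dist.copies) == 0

    def test_percentages_sum_to_hundred(self, small_sim):
        for res in small_sim.results.values():
            dist = abundance_distribution(res.clean)
            assert sum(dist.pct_distinct) == pytest.approx(100.0, abs=1e-9)
            assert sum(dist.pct_copies) == pytest.approx(100.0, abs=1e-9)
            assert sum(dist.distinct) == res.clean.distinct
            assert sum(dist.copies) == res.clean.total

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ValueError):
            abundance_distribution(clean_lib({T[0]: 2}), [(2, 10), (5, 20)])

    def test_count_outside_bins_rejected(self):
        with pytest.raises(ValueError):
            abundance_distribution(clean_lib({T[0]: 2}), [(5, None)])


class TestSaturation:
    def test_full_depth_detects_all_unambiguous_genes(self, small_sim):
        res = small_sim.results["Br"]
        curve = saturation_curve(res.clean, res.assignments, step=5000, seed=0)
        assert curve.points[-1][0] == res.clean.total
        assert curve.points[-1][1] == res.summary.unambiguous_tag_mapped_genes

    def test_monotone_for_any_seed(self, small_sim):
        res = small_sim.results["Br"]
        for seed in range(3):
            curve = saturation_curve(res.clean, res.assignments, step=3000, seed=seed)
            detected = [d for _, d in curve.points]
            assert detected == sorted(detected)

    def test_depth_one_matches_analytic_probability(self, toy_assignments):
        """Two-gene toy: detection at depth 1 = mapped copies / total copies."""
        lib, assignments = toy_assignments
        expected = 4 / 6  # 4 of 6 copies carry an unambiguous gene
        draws = [
            saturation_curve(lib, assignments, step=1, seed=s).points[0][1]
            for s in range(400)
        ]
        assert np.mean(draws) == pytest.approx(expected, abs=0.08)

    def test_bad_step_rejected(self, small_sim):
        res = small_sim.results["Br"]
        with pytest.raises(ValueError):
            saturation_curve(res.clean, res.assignments, step=0, seed=0)


@pytest.fixture()
def toy_assignments():
    from dgetags.tag_mapping import TagAssignment

    lib = clean_lib({T[0]: 3, T[1]: 1, T[2]: 2})
    assignments = [
        TagAssignment(T[0], 3, "gene_unambiguous", "gA", "sense", "exact", frozenset({"gA"})),
        TagAssignment(T[1], 1, "gene_unambiguous", "gB", "sense", "exact", frozenset({"gB"})),
        TagAssignment(T[2], 2, "unknown", None, None, "none"),
    ]
    return lib, assignments


class TestRatio:
    def test_identical_libraries_all_first_bin(self):
        lib = clean_lib({T[0]: 10, T[1]: 55})
        dist = ratio_distribution(lib, clean_lib(dict(lib.counts), "y"))
        assert dist.fractions["[1,2)"] == 1.0

    def test_arithmetic_example(self):
        a = clean_lib({T[0]: 10, T[1]: 90}, "a")  # equal totals: raw = normalized
        b = clean_lib({T[0]: 55, T[1]: 45}, "b")
        dist = ratio_distribution(a, b)
        assert dist.fractions[">5"] == pytest.approx(0.5)  # 10 vs 55
        assert dist.fractions["[2,3)"] == pytest.approx(0.5)  # 90 vs 45

    def test_hand_computed_toy(self):
        a = clean_lib({T[0]: 4, T[1]: 8, T[2]: 10}, "a")
        b = clean_lib({T[0]: 4, T[1]: 32, T[3]: 7}, "b")
        # totals: 22 vs 43; normalized ratios fold to:
        # T0: (4/22)/(4/43) = 43/22 = 1.95 -> [1,2)
        # T1: (32/43)/(8/22) = 2.047 -> [2,3)
        dist = ratio_distribution(a, b)
        assert dist.fractions["[1,2)"] == pytest.approx(0.5)
        assert dist.fractions["[2,3)"] == pytest.approx(0.5)
        assert dist.n_a_only == 1 and dist.n_b_only == 1

    def test_shared_fractions_sum_to_one(self, small_sim):
        a = small_sim.results["Br"].clean
        b = small_sim.results["F1"].clean
        dist = ratio_distribution(a, b)
        assert sum(dist.fractions.values()) == pytest.approx(1.0)


class TestOverlaps:
    def test_two_set_example(self):
        ov = expression_overlaps({"A": {"g1", "g2"}, "B": {"g2", "g3"}})
        assert ov.region("A") == 1
        assert ov.region("B") == 1
        assert ov.region("A", "B") == 1

    def test_disjoint_sets(self):
        ov = expression_overlaps({"A": {"g1"}, "B": {"g2"}})
        assert ov.region("A", "B") == 0

    def test_region_sums_equal_union(self):
        rng = np.random.default_rng(1)
        universe = [f"g{i}" for i in range(200)]
        sets = {
            name: set(rng.choice(universe, size=rng.integers(20, 120), replace=False))
            for name in "ABCD"
        }
        ov = expression_overlaps(sets)
        assert ov.union_size == len(set.union(*sets.values()))
        # every set's size is recoverable from its regions
        for name in sets:
            total = sum(
                count for region, count in ov.regions.items() if name in region
            )
            assert total == len(sets[name])

    def test_too_many_sets_rejected(self):
        with pytest.raises(ValueError):
            expression_overlaps({n: {"g"} for n in "ABCDE"})


class TestClustering:
    def test_identical_rows_merge_first_at_zero(self):
        mat = pd.DataFrame(
            [[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]], index=["a", "b", "c"]
        )
        tree = cluster_degs(mat, n_clusters=2)
        first = tree.merges[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == 0.0
        assert tree.labels["a"] == tree.labels["b"] != tree.labels["c"]

    def test_one_dimensional_toy_matches_brute_force(self):
        # points 0, 1, 10, 11 with average linkage: merge (0,1) and (10,11)
        # at height 1, then the pair means 0.5 and 10.5 at height 10
        mat = pd.DataFrame([[0.0], [1.0], [10.0], [11.0]], index=list("abcd"))
        tree = cluster_degs(mat, n_clusters=2)
        heights = tree.merges[:, 2].tolist()
        assert heights[:2] == [1.0, 1.0]
        assert heights[2] == pytest.approx(10.0)
        assert tree.labels["a"] == tree.labels["b"]
        assert tree.labels["c"] == tree.labels["d"]
        assert tree.labels["a"] != tree.labels["c"]

    def test_permutation_invariant_partition(self):
        rng = np.random.default_rng(2)
        base = np.vstack(
            [rng.normal(mu, 0.3, size=(10, 4)) for mu in (-2.0, 0.0, 2.0)]
        )
        genes = [f"g{i}" for i in range(30)]
        mat = pd.DataFrame(base, index=genes)
        perm = rng.permutation(30)
        shuffled = mat.iloc[perm]
        t1 = cluster_degs(mat, n_clusters=3)
        t2 = cluster_degs(shuffled, n_clusters=3)
        from sklearn.metrics import adjusted_rand_score

        aligned = t2.labels.reindex(t1.labels.index)
        assert adjusted_rand_score(t1.labels, aligned) == 1.0

    def test_planted_groups_recovered(self):
        """Planted DEG response groups are recovered at the true cluster count.

        Emulates the dominant hybrid pattern: one group up in F1 against the
        parents then reverting in F2-F4, one group doing the opposite, one
        flat group.
        """
        rng = np.random.default_rng(3)
        profiles = {
            "up_then_down": [2.5, 2.5, -2.0, -2.0, -2.0],
            "down_then_up": [-2.5, -2.5, 2.0, 2.0, 2.0],
            "flat_up": [1.0, 1.0, 1.0, 1.0, 1.0],
        }
        rows, labels = [], []
        for name, centre in profiles.items():
            for _ in range(25):
                rows.append(np.asarray(centre) + rng.normal(0, 0.4, 5))
                labels.append(name)
        mat = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))])
        tree = cluster_degs(mat, n_clusters=3)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels, tree.labels) >= 0.8

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            cluster_degs(pd.DataFrame())

    def test_cluster_means_shape(self):
        mat = pd.DataFrame(np.eye(4), index=list("abcd"))
        tree = cluster_degs(mat, n_clusters=2)
        assert set(tree.means.index) == set(tree.labels.unique())


class TestEnrichment:
    def test_matches_enumeration_oracle(self):
        # N=10, K=4, n=5, k=3: upper tail by direct support enumeration
        gene_to_terms = {f"g{i}": {"T"} for i in range(4)}
        background = {f"g{i}" for i in range(10)}
        foreground = {"g0", "g1", "g2", "g5", "g6"}  # k = 3
        (rec,) = term_enrichment(foreground, background, gene_to_terms)
        oracle = sum(
            math.comb(4, j) * math.comb(6, 5 - j) / math.comb(10, 5)
            for j in range(3, 5)
        )
        assert rec.p_value == pytest.approx(oracle, rel=1e-12)
        assert (rec.k, rec.K, rec.n, rec.N) == (3, 4, 5, 10)

    def test_term_covering_background_is_null(self):
        background = {f"g{i}" for i in range(8)}
        gene_to_terms = {g: {"ALL"} for g in background}
        (rec,) = term_enrichment({"g0", "g1"}, background, gene_to_terms)
        assert rec.p_value == pytest.approx(1.0)

    def test_foreground_equals_background_is_null(self):
        background = {f"g{i}" for i in range(6)}
        gene_to_terms = {"g0": {"T1"}, "g1": {"T1"}, "g2": {"T2"}}
        records = term_enrichment(background, background, gene_to_terms)
        assert all(r.p_value == pytest.approx(1.0) for r in records)
        assert all(r.k == r.K for r in records)

    def test_foreground_outside_background_rejected(self):
        with pytest.raises(ValueError):
            term_enrichment({"x"}, {"y"}, {})


class TestDegMatrix:
    def test_union_and_intersection(self):
        from dgetags.differential_expression import ComparisonResult, DEGRecord

        def rec(gene, l2r, sig):
            return DEGRecord(
                gene, 1, 1, 1, 1, l2r, 0.001, 0.0001 if sig else 0.5, sig,
                "up" if sig and l2r > 0 else ("down" if sig else "none"),
            )

        r1 = ComparisonResult("A", "B", [rec("g1", 2, True), rec("g2", 1.5, True)])
        r2 = ComparisonResult("A", "C", [rec("g2", -2, True), rec("g3", 3, True)])
        union = deg_log2_matrix([r1, r2], mode="union")
        inter = deg_log2_matrix([r1, r2], mode="intersection")
        assert set(union.index) == {"g1", "g2", "g3"}
        assert set(inter.index) == {"g2"}
        assert union.loc["g1", "A vs C"] == 0.0  # untested cell imputed
        with pytest.raises(ValueError):
            deg_log2_matrix([r1], mode="bogus")
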
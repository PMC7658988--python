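import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromclust import (
    FeatureSet,
    GenomicInterval,
    ValidationError,
    associate_genes,
    enrich_gene_sets,
    hypergeometric_overrep,
    merge_close_intervals,
    read_gmt,
)
from chromclust.enrichment import read_gene_annotation
from oracles import hypergeom_enumeration


def iv(start, end, chrom="chrA"):
    return GenomicInterval(chrom, start, end)


class TestMergeCloseIntervals:
    def test_merges_below_gap(self):
        merged = merge_close_intervals([iv(0, 100), iv(4000, 4100)], gap=5000)
        assert [(m.start, m.end) for m in merged] == [(0, 4100)]

    def test_keeps_distant_intervals(self):
        merged = merge_close_intervals([iv(0, 100), iv(10_000, 10_100)], gap=5000)
        assert len(merged) == 2

    def test_single_interval_identity(self):
        merged = merge_close_intervals([iv(5, 10)])
        assert [(m.start, m.end) for m in merged] == [(5, 10)]

    def test_different_chromosomes_never_merge(self):
        merged = merge_close_intervals([iv(0, 100), iv(200, 300, chrom="chrB")], gap=5000)
        assert len(merged) == 2

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_idempotent_with_min_gap(self, seed):
        rng = np.random.default_rng(seed)
        intervals = [
            iv(int(s), int(s) + int(rng.integers(1, 2000)))
            for s in rng.integers(0, 100_000, size=15)
        ]
        gap = 3000
        merged = merge_close_intervals(intervals, gap=gap)
        again = merge_close_intervals(merged, gap=gap)
        assert [(m.chrom, m.start, m.end) for m in merged] == [
            (m.chrom, m.start, m.end) for m in again
        ]
        for a, b in zip(merged, merged[1:]):
            if a.chrom == b.chrom:
                assert b.start - a.end >= gap


class TestAssociateGenes:
    @staticmethod
    def ann(rows):
        return pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand", "biotype"])

    features = FeatureSet([iv(0, 50_000)], mode="peaks")

    def test_tss_just_downstream_is_associated(self):
        assoc = associate_genes(
            self.features, self.ann([("g1", "chrA", 50_500, "+", "protein_coding")]), 1000
        )
        assert assoc == {0: ["g1"]}

    def test_tss_beyond_max_dist_not_associated(self):
        assoc = associate_genes(
            self.features, self.ann([("g1", "chrA", 51_500, "+", "protein_coding")]), 1000
        )
        assert assoc == {}

    def test_tss_inside_feature_always_associated(self):
        assoc = associate_genes(
            self.features, self.ann([("g1", "chrA", 25_000, "+", "protein_coding")]), 0
        )
        assert assoc == {0: ["g1"]}

    def test_unknown_chromosome_skipped(self):
        assoc = associate_genes(
            self.features, self.ann([("g1", "chrZ", 10, "+", "protein_coding")]), 1000
        )
        assert assoc == {}


class TestHypergeometric:
    def test_closed_form_example(self):
        # C(5,4) * C(5,0) / C(10,4) = 5/210
        assert hypergeometric_overrep(4, 5, 4, 10) == pytest.approx(5 / 210)

    def test_zero_overlap_gives_one(self):
        assert hypergeometric_overrep(0, 5, 4, 10) == 1.0

    def test_query_is_everything(self):
        assert hypergeometric_overrep(3, 3, 10, 10) == pytest.approx(1.0)

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ValidationError):
            hypergeometric_overrep(5, 4, 4, 10)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_subset_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(4, 13))
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        k = int(rng.integers(0, min(K, n) + 1))
        assert hypergeometric_overrep(k, K, n, N) == pytest.approx(
            hypergeom_enumeration(k, K, n, N), abs=1e-12
        )

    def test_monotone_in_overlap(self):
        ps = [hypergeometric_overrep(k, 10, 15, 60) for k in range(0, 11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestEnrichGeneSets:
    universe = [f"G{i:03d}" for i in range(200)]

    def test_query_equals_universe_all_p_one(self):
        sets = {"S1": self.universe[:20], "S2": self.universe[50:70]}
        table = enrich_gene_sets(self.universe, self.universe, sets)
        assert (table["p"] == 1.0).all()

    def test_planted_set_ranks_first(self):
        planted = self.universe[:20]
        sets = {"PLANTED": planted}
        rng = np.random.default_rng(0)
        for d in range(5):
            sets[f"DECOY{d}"] = list(rng.choice(self.universe, 20, replace=False))
        table = enrich_gene_sets(planted, self.universe, sets)
        assert table.iloc[0]["set"] == "PLANTED"
        # minimum achievable p for a fully contained set: 1 / C(200, 20)
        expected = float(np.exp(np.sum(np.log(np.arange(1, 21)) - np.log(np.arange(181, 201)))))
        assert table.iloc[0]["p"] == pytest.approx(expected, rel=1e-6)

    def test_bh_reused_across_sets(self):
        from chromclust import bh_adjust

        sets = {"A": self.universe[:10], "B": self.universe[10:40], "C": self.universe[40:45]}
        table = enrich_gene_sets(self.universe[:12], self.universe, sets)
        np.testing.assert_allclose(
            np.sort(table["q"]), np.sort(bh_adjust(table["p"].to_numpy()))
        )

    def test_sets_outside_universe_skipped_and_query_intersected(self):
        sets = {"OUT": ["ZZZ1", "ZZZ2"], "IN": self.universe[:5]}
        table = enrich_gene_sets(self.universe[:5] + ["ZZZ1"], self.universe, sets)
        assert list(table["set"]) == ["IN"]
        assert table.iloc[0]["n"] == 5

    def test_case_insensitive_matching(self):
        table = enrich_gene_sets(["g000"], self.universe, {"S": ["G000"]})
        assert table.iloc[0]["k"] == 1

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            enrich_gene_sets(["a"], [], {"S": ["a"]})

    def test_adding_query_gene_never_raises_p(self):
        sets = {"S": self.universe[:20]}
        query = list(self.universe[:5])
        prev = enrich_gene_sets(query, self.universe, sets).iloc[0]["p"]
        for extra in self.universe[5:10]:
            query.append(extra)
            p = enrich_gene_sets(query, self.universe, sets).iloc[0]["p"]
            assert p <= prev + 1e-12
            prev = p


class TestFileReaders:
    def test_gmt_roundtrip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("SET1\tdesc\tGeneA\tGeneB\nSET2\tdesc\tGeneC\n")
        sets = read_gmt(path)
        assert sets == {"SET1": ["GENEA", "GENEB"], "SET2": ["GENEC"]}

    def test_gmt_rejects_empty_set(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("SET1\tdesc\n")
        with pytest.raises(ValidationError):
            read_gmt(path)

    def test_annotation_biotype_filter(self, tmp_path):
        path = tmp_path / "ann.tsv"
        pd.DataFrame(
            {
                "gene": ["a", "b", "c"],
                "chrom": ["chr1"] * 3,
                "tss": [1, 2, 3],
                "strand": ["+"] * 3,
                "biotype": ["protein_coding", "miRNA", "lncRNA"],
            }
        ).to_csv(path, sep="\t", index=False)
        ann = read_gene_annotation(path)
        assert list(ann["gene"]) == ["a", "c"]
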
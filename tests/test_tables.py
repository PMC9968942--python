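"""Data model: readers, lineage parsing, rarefaction, aggregation, venn."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutassembly import (OtuTable, aggregate_by_rank, filter_to_domain,
                         parse_lineage, rarefy, read_otu_table,
                         site_taxon_sets, venn_counts)
from gutassembly.tables import LineageParseError, TableValidationError

from conftest import build_table


class TestReaders:
    def test_toy_trio_depths(self, toy_tsvs):
        table = read_otu_table(*toy_tsvs)
        assert list(table.depth) == [6, 9]
        assert table.n_taxa == 3 and table.n_samples == 2

    def test_genus_placeholder_retained(self, toy_tsvs):
        table = read_otu_table(*toy_tsvs)
        assert table.lineages.loc["OTU1", "genus"] == ""
        assert table.lineages.loc["OTU1", "family"] == "Oscillospiraceae"
        # placeholder family labels survive verbatim
        assert table.lineages.loc["OTU3", "family"] == "norank_o__Clostridia_UCG-014"

    def test_missing_metadata_sample_listed(self, toy_tsvs, tmp_path):
        counts, taxonomy, _ = toy_tsvs
        bad_meta = tmp_path / "meta_bad.tsv"
        bad_meta.write_text("sample_id\tsite\tsocial_group\nA\tsiteA\tg1\n")
        with pytest.raises(TableValidationError, match="B"):
            read_otu_table(counts, taxonomy, bad_meta)

    def test_non_integer_counts_rejected(self, toy_tsvs, tmp_path):
        _, taxonomy, metadata = toy_tsvs
        bad = tmp_path / "counts_bad.tsv"
        bad.write_text("otu_id\tA\tB\nOTU1\t3.5\t2\nOTU2\t2\t3\nOTU3\t1\t4\n")
        with pytest.raises(TableValidationError, match="non-integer"):
            read_otu_table(bad, taxonomy, metadata)

    def test_malformed_lineage_names_otu(self):
        with pytest.raises(LineageParseError, match="OTU9"):
            parse_lineage("", "OTU9")

    def test_biom_tsv_dialect(self, toy_tsvs, tmp_path):
        _, taxonomy, metadata = toy_tsvs
        biom = tmp_path / "counts_biom.tsv"
        biom.write_text("# Constructed from biom file\n"
                        "#OTU ID\tA\tB\nOTU1\t3\t2\nOTU2\t2\t3\nOTU3\t1\t4\n")
        table = read_otu_table(biom, taxonomy, metadata)
        assert list(table.depth) == [6, 9]

    def test_round_trip_archive(self, ten_otu_table, tmp_path):
        ten_otu_table.to_dir(tmp_path / "arc")
        back = OtuTable.from_dir(tmp_path / "arc")
        pd.testing.assert_frame_equal(back.counts, ten_otu_table.counts)
        pd.testing.assert_frame_equal(back.lineages, ten_otu_table.lineages)
        pd.testing.assert_frame_equal(back.meta, ten_otu_table.meta)


class TestDomainFilter:
    def test_filters_non_bacterial(self):
        t = build_table(np.ones((6, 4), dtype=int),
                        domains=["Bacteria"] * 5 + ["Archaea"])
        out = filter_to_domain(t, "Bacteria")
        assert out.n_taxa == 5

    def test_identity_on_all_bacteria(self, ten_otu_table):
        out = filter_to_domain(ten_otu_table, "Bacteria")
        pd.testing.assert_frame_equal(out.counts, ten_otu_table.counts)

    def test_empty_result_errors(self, ten_otu_table):
        with pytest.raises(TableValidationError):
            filter_to_domain(ten_otu_table, "Archaea")


class TestRarefy:
    def test_conserves_depth_and_exhaustive_case(self, ten_otu_table):
        full = int(ten_otu_table.depth.min())
        out = rarefy(ten_otu_table, full, seed=1)
        # subsampling all reads returns the column unchanged
        pd.testing.assert_frame_equal(out.counts, ten_otu_table.counts)
        out = rarefy(ten_otu_table, 40, seed=1)
        assert (out.depth == 40).all()
        assert (out.counts.to_numpy() <= ten_otu_table.counts.to_numpy()).all()

    def test_seed_reproducibility(self, ten_otu_table):
        a = rarefy(ten_otu_table, 50, seed=7)
        b = rarefy(ten_otu_table, 50, seed=7)
        c = rarefy(ten_otu_table, 50, seed=8)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        assert not a.counts.equals(c.counts)

    def test_depth_exceeding_sample_names_it(self, ten_otu_table):
        with pytest.raises(TableValidationError, match="S1"):
            rarefy(ten_otu_table, 101, seed=0)

    def test_expected_counts_match_hypergeometric_mean(self):
        t = build_table(np.array([[50], [30], [20]]), sites=["siteA"],
                        groups=["g1"])
        depth, n_seeds = 40, 200
        acc = np.zeros(3)
        for s in range(n_seeds):
            acc += rarefy(t, depth, seed=s).counts.to_numpy().ravel()
        mean = acc / n_seeds
        expected = np.array([50, 30, 20]) * depth / 100
        # multivariate-hypergeometric sd per taxon < 2.5; 4 se tolerance
        assert np.all(np.abs(mean - expected) < 4 * 2.5 / np.sqrt(n_seeds))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.integers(0, 60), min_size=3, max_size=8).filter(lambda c: sum(c) >= 10),
           st.integers(0, 10_000))
    def test_rarefaction_invariants(self, column, seed):
        t = build_table(np.array(column)[:, None], sites=["siteA"], groups=["g1"])
        out = rarefy(t, 10, seed=seed)
        assert out.depth.iloc[0] == 10
        assert (out.counts.to_numpy() <= t.counts.to_numpy()).all()
        assert (out.counts.to_numpy() >= 0).all()


class TestAggregate:
    def test_sums_and_depth_preserved(self, ten_otu_table):
        agg = aggregate_by_rank(ten_otu_table, "phylum")
        assert agg.n_taxa == 3
        pd.testing.assert_series_equal(agg.depth, ten_otu_table.depth)
        # hand summation: Firmicutes = OTU1..5
        hand = ten_otu_table.counts.iloc[:5].sum(axis=0)
        pd.testing.assert_series_equal(agg.counts.loc["Firmicutes"], hand,
                                       check_names=False)

    def test_idempotent_at_same_rank(self, ten_otu_table):
        agg = aggregate_by_rank(ten_otu_table, "family")
        again = aggregate_by_rank(agg, "family")
        pd.testing.assert_frame_equal(agg.counts, again.counts)

    def test_unknown_rank_errors(self, ten_otu_table):
        with pytest.raises(ValueError, match="rank"):
            aggregate_by_rank(ten_otu_table, "kingdom")


class TestVenn:
    @pytest.mark.parametrize("a,b,expected", [
        ({"x", "y", "z"}, {"x", "y", "z"}, (3, 0, 0)),
        ({"x", "y"}, {"z", "w"}, (0, 2, 2)),
        ({"x", "y", "z"}, {"y", "z", "w"}, (2, 1, 1)),
    ])
    def test_counts(self, a, b, expected):
        v = venn_counts(a, b)
        assert tuple(v) == expected
        assert v.shared + v.unique_a == len(a)
        assert v.shared + v.unique_b == len(b)

    def test_site_sets_presence(self, ten_otu_table):
        sets = site_taxon_sets(ten_otu_table, "phylum")
        assert set(sets) == {"siteA", "siteB"}
        assert all(s <= {"Firmicutes", "Bacteroidetes", "Actinobacteria"}
                   for s in sets.values())
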
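"""Composition summaries, F/B ratios, and rank-sum differential abundance."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gutassembly import (diff_abundance, fb_ratio, summarize_composition,
                         weighted_overall_ratio)

from conftest import build_table


class TestSummary:
    def test_single_taxon_per_sample(self):
        t = build_table(np.array([[50, 80]]), sites=["siteA", "siteB"])
        s = summarize_composition(t, "phylum")
        assert s.site_mean.loc["Firmicutes"].tolist() == [1.0, 1.0]
        assert np.allclose(s.others_by_site.to_numpy(), 0.0)

    def test_others_bucket_arithmetic(self):
        # fixed composition 0.60 / 0.35 / 10 x 0.005 in every sample
        rel = [0.60, 0.35] + [0.005] * 10
        counts = np.tile((np.array(rel) * 1000).astype(int)[:, None], (1, 4))
        phyla = [f"P{i}" for i in range(12)]
        t = build_table(counts, phyla=phyla)
        s = summarize_composition(t, "phylum", threshold=0.01)
        assert sorted(s.displayed_taxa) == ["P0", "P1"]
        assert np.allclose(s.others_by_site.to_numpy(), 0.05)

    def test_hand_computed_two_site_means(self):
        counts = np.array([[60, 40, 80, 20],
                           [40, 60, 20, 80]])
        t = build_table(counts, phyla=["Firmicutes", "Bacteroidetes"],
                        sites=["siteA", "siteA", "siteB", "siteB"])
        s = summarize_composition(t, "phylum")
        assert s.site_mean.loc["Firmicutes", "siteA"] == pytest.approx(0.5)
        assert s.site_sd.loc["Firmicutes", "siteA"] == pytest.approx(
            np.std([0.6, 0.4], ddof=1))
        assert s.site_mean.loc["Firmicutes", "siteB"] == pytest.approx(0.5)
        assert s.site_sd.loc["Bacteroidetes", "siteB"] == pytest.approx(
            np.std([0.2, 0.8], ddof=1))

    def test_per_sample_fractions_sum_to_one(self, ten_otu_table):
        s = summarize_composition(ten_otu_table, "family")
        assert np.allclose(s.rel_abundance.sum(axis=0).to_numpy(), 1.0, atol=1e-9)


class TestFbRatio:
    def test_equal_means_ratio_one(self):
        counts = np.array([[50, 50], [50, 50]])
        t = build_table(counts, phyla=["Firmicutes", "Bacteroidetes"],
                        sites=["siteA", "siteB"])
        fb = fb_ratio(summarize_composition(t, "phylum"))
        assert fb.per_site["siteA"] == pytest.approx(1.0)
        assert fb.overall_weighted == pytest.approx(1.0)

    def test_weighted_overall_from_group_summaries(self):
        # two sites with known means and 155/48 sample weights
        overall = weighted_overall_ratio(
            mean_f={"a": 0.8630, "b": 0.7885},
            mean_b={"a": 0.0475, "b": 0.1365},
            n={"a": 155, "b": 48})
        f = (155 * 0.8630 + 48 * 0.7885) / 203
        b = (155 * 0.0475 + 48 * 0.1365) / 203
        assert overall == pytest.approx(f / b, rel=1e-12)

    def test_mean_of_ratios_vs_brute_force(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(1, 200, size=(4, 6))
        t = build_table(counts, phyla=["Firmicutes", "Bacteroidetes",
                                       "Actinobacteria", "Proteobacteria"])
        fb = fb_ratio(summarize_composition(t, "phylum"))
        brute = np.mean(counts[0] / counts[1])
        assert fb.overall_mean_of_ratios == pytest.approx(brute, rel=1e-12)

    def test_zero_bacteroidetes_flagged(self):
        counts = np.array([[50, 50], [0, 0], [10, 10]])
        t = build_table(counts, phyla=["Firmicutes", "Bacteroidetes",
                                       "Actinobacteria"],
                        sites=["siteA", "siteB"])
        fb = fb_ratio(summarize_composition(t, "phylum"))
        assert fb.flagged
        assert np.isinf(fb.per_site["siteA"])

    def test_missing_phylum_errors(self, ten_otu_table):
        s = summarize_composition(ten_otu_table, "family")
        with pytest.raises(KeyError):
            fb_ratio(s)


class TestDiffAbundance:
    def test_identical_groups_p_one(self):
        counts = np.tile(np.array([[30], [70]]), (1, 6))
        t = build_table(counts, phyla=["P1", "P2"])
        da = diff_abundance(t, "phylum")
        assert (da["pvalue"] == 1.0).all()
        assert da["constant"].all()

    def test_fully_separated_exact_p(self):
        # 3 vs 3 with complete separation: two-sided exact p = 2/C(6,3) = 0.1
        counts = np.array([
            [10, 20, 30, 40, 50, 60],
            [90, 80, 70, 60, 50, 40],
        ])
        t = build_table(counts, phyla=["P1", "P2"],
                        sites=["siteA"] * 3 + ["siteB"] * 3)
        da = diff_abundance(t, "phylum")
        assert da.loc["P1", "pvalue"] == pytest.approx(0.1)

    def test_exact_matches_enumeration_oracle(self):
        # brute-force two-sided rank-sum p by enumerating all C(7,3) splits
        x = np.array([0.11, 0.23, 0.35])
        y = np.array([0.18, 0.27, 0.40, 0.52])
        pooled = np.concatenate([x, y])

        def u_stat(xv, yv):
            return sum((xi > yj) + 0.5 * (xi == yj) for xi in xv for yj in yv)

        obs = u_stat(x, y)
        n = len(pooled)
        mu = len(x) * len(y) / 2
        count = total = 0
        for idx in itertools.combinations(range(n), len(x)):
            xv = pooled[list(idx)]
            yv = np.delete(pooled, list(idx))
            total += 1
            if abs(u_stat(xv, yv) - mu) >= abs(obs - mu) - 1e-12:
                count += 1
        exact_p = count / total

        counts = np.vstack([
            (np.concatenate([x, y]) * 100).astype(int),
            (100 - np.concatenate([x, y]) * 100).astype(int),
        ])
        t = build_table(counts, phyla=["P1", "P2"],
                        sites=["siteA"] * 3 + ["siteB"] * 4)
        da = diff_abundance(t, "phylum")
        assert da.loc["P1", "pvalue"] == pytest.approx(exact_p, abs=1e-9)

    def test_bh_monotone_and_bounded(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 100, size=(40, 12)) + 1
        t = build_table(counts, phyla=[f"P{i}" for i in range(40)])
        da = diff_abundance(t, "phylum")
        assert (da["pvalue_corrected"] >= da["pvalue"] - 1e-15).all()
        assert (da["pvalue_corrected"] <= 1.0).all()
        ordered = da.sort_values("pvalue")
        assert (np.diff(ordered["pvalue_corrected"].to_numpy()) >= -1e-12).all()

    def test_single_taxon_bh_identity(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(1, 100, size=(1, 10))
        t = build_table(counts, phyla=["P1"])
        da = diff_abundance(t, "phylum")
        assert da["pvalue_corrected"].iloc[0] == pytest.approx(da["pvalue"].iloc[0])

    def test_correction_choices(self, ten_otu_table):
        bh = diff_abundance(ten_otu_table, "phylum", correction="bh")
        bonf = diff_abundance(ten_otu_table, "phylum", correction="bonferroni")
        assert (bonf["pvalue_corrected"] >= bh["pvalue_corrected"] - 1e-12).all()
        with pytest.raises(ValueError):
            diff_abundance(ten_otu_table, "phylum", correction="nope")
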
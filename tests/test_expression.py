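"""Quantification, maternal exclusion, clustering, intergenic ratio, profiles."""

import numpy as np
import pandas as pd
import pytest

from zgakit.expression import (
    ExpressionMatrix,
    assign_clusters,
    compute_cpm,
    compute_tpm,
    exclude_maternal,
    gene_body_density,
    intergenic_ratio,
    kd_response,
    metaprofile,
    spearman_deposition_vs_change,
)
from zgakit.genome import GenomicInterval, IntervalSet


def em(counts: dict, lengths: dict | None = None) -> ExpressionMatrix:
    data = pd.DataFrame(counts)
    lens = pd.Series(lengths, dtype=float) if lengths else None
    return ExpressionMatrix(data=data, lengths=lens)


class TestTpmCpm:
    def test_equal_rates_split_the_million(self):
        t = compute_tpm(em({"s": {"A": 10, "B": 30}}, {"A": 1000, "B": 3000}))
        assert t.data["s"].tolist() == [500_000.0, 500_000.0]

    def test_single_feature_gets_all(self):
        t = compute_tpm(em({"s": {"A": 7}}, {"A": 500}))
        assert t.data["s"].iloc[0] == 1e6

    def test_hand_computed_rates(self):
        # rates 20/1000 = 0.02 and 30/3000 = 0.01 -> 2/3 and 1/3 of 1e6
        t = compute_tpm(em({"s": {"A": 20, "B": 30}}, {"A": 1000, "B": 3000}))
        assert np.allclose(t.data["s"].tolist(), [2e6 / 3, 1e6 / 3])

    def test_all_zero_sample_names_sample(self):
        with pytest.raises(ValueError, match="bad_sample"):
            compute_tpm(em({"bad_sample": {"A": 0}}, {"A": 100}))

    def test_cpm_proportional(self):
        c = compute_cpm(em({"s": {"r1": 1, "r2": 3}}))
        assert c.data["s"].tolist() == [250_000.0, 750_000.0]

    def test_cpm_scale_invariance(self, rng):
        counts = pd.DataFrame({"s": rng.integers(1, 100, 20).astype(float)})
        a = compute_cpm(ExpressionMatrix(counts))
        b = compute_cpm(ExpressionMatrix(counts * 2))
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_columns_sum_to_one_million(self, rng):
        counts = pd.DataFrame(rng.integers(0, 1000, (50, 4)).astype(float))
        counts.iloc[0] += 1  # no all-zero column
        lengths = pd.Series(rng.integers(200, 20_000, 50).astype(float))
        for norm in (compute_tpm(ExpressionMatrix(counts, lengths)),
                     compute_cpm(ExpressionMatrix(counts))):
            assert np.allclose(norm.data.sum(axis=0), 1e6, rtol=1e-9)


class TestMaternalExclusion:
    def make(self, mii, early, late):
        return pd.DataFrame(
            {"MII": [mii], "early2C": [early], "late2C": [late]}, index=["g"]
        )

    @pytest.mark.parametrize(
        "vals, excluded",
        [
            ((100, 50, 10), True),    # strictly decreasing -> maternal
            ((10, 50, 100), False),   # increasing -> embryonic
            ((100, 120, 10), False),  # rebound at early2C -> embryonic
            ((100, 100, 10), False),  # tie is not a strict decrease
        ],
    )
    def test_rule(self, vals, excluded):
        got = exclude_maternal(self.make(*vals))
        assert (len(got) == 1) == excluded

    def test_ends_only_mode(self):
        got = exclude_maternal(self.make(100, 120, 10), mode="ends_only")
        assert len(got) == 1

    def test_missing_stage_errors(self):
        with pytest.raises(ValueError, match="late2C"):
            exclude_maternal(pd.DataFrame({"MII": [1], "early2C": [2]}))


class TestClusters:
    def test_examples(self):
        early = pd.Series({"up": 10.0, "flat": 30.0, "down": 40.0})
        late = pd.Series({"up": 40.0, "flat": 30.0, "down": 10.0})
        ca = assign_clusters(early, late, pseudocount=1.0)
        assert ca.table.loc["up", "cluster"] == "I"
        assert np.isclose(ca.table.loc["up", "log2_ratio"], np.log2(41 / 11))
        assert ca.table.loc["flat", "cluster"] == "II"
        assert ca.table.loc["flat", "log2_ratio"] == 0.0
        assert ca.table.loc["down", "cluster"] == "III"

    def test_threshold_tie_goes_to_cluster_II(self):
        # with thresholds at +-1 and pc=1, ratio exactly 2 sits on the boundary
        early = pd.Series({"g": 1.0})
        late = pd.Series({"g": 3.0})
        ca = assign_clusters(early, late, lo=-1.0, hi=1.0, pseudocount=1.0)
        assert ca.table.loc["g", "log2_ratio"] == 1.0
        assert ca.table.loc["g", "cluster"] == "II"

    def test_negative_abundance_errors(self):
        with pytest.raises(ValueError):
            assign_clusters(pd.Series({"g": -1.0}), pd.Series({"g": 1.0}))

    def test_exhaustive_exclusive_and_permutation_invariant(self, rng):
        n = 200
        idx = [f"g{i}" for i in range(n)]
        early = pd.Series(rng.uniform(0, 100, n), index=idx)
        late = pd.Series(rng.uniform(0, 100, n), index=idx)
        ca = assign_clusters(early, late)
        assert set(ca.table["cluster"]) <= {"I", "II", "III"}
        assert sum(ca.sizes().values()) == n
        perm = rng.permutation(idx)
        ca2 = assign_clusters(early.loc[perm], late.loc[perm])
        pd.testing.assert_series_equal(
            ca.table["cluster"].sort_index(), ca2.table["cluster"].sort_index()
        )


class TestKdResponse:
    def make_clusters(self):
        early = pd.Series({"a": 10.0, "b": 10.0})
        late = pd.Series({"a": 100.0, "b": 1.0})
        return assign_clusters(early, late)

    def test_identity_and_doubling(self):
        ca = self.make_clusters()
        same, _ = kd_response(pd.Series({"a": 5.0, "b": 7.0}),
                              pd.Series({"a": 5.0, "b": 7.0}), ca)
        assert (same["log2_kd_over_ctrl"] == 0).all()
        doubled, _ = kd_response(pd.Series({"a": 10.0, "b": 14.0}),
                                 pd.Series({"a": 5.0, "b": 7.0}), ca, pseudocount=0.0)
        assert np.allclose(doubled["log2_kd_over_ctrl"], 1.0)

    def test_empty_cluster_reported_with_size_zero(self):
        ca = self.make_clusters()  # only clusters I and III populated
        _, summary = kd_response(pd.Series({"a": 1.0, "b": 1.0}),
                                 pd.Series({"a": 1.0, "b": 1.0}), ca)
        assert summary.loc["II", "n"] == 0
        assert np.isnan(summary.loc["II", "median"])


class TestIntergenicRatio:
    def test_counting(self):
        iset = IntervalSet({"chr1": [(0, 10_000)]})
        rows = [("chr1", i * 10, i * 10 + 100) for i in range(50)]          # inside
        rows += [("chr2", 0, 100)] * 150                                     # outside
        frags = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        assert intergenic_ratio(frags, iset) == 0.25

    def test_no_intervals_gives_zero(self):
        frags = pd.DataFrame([("chr1", 0, 100)], columns=["chrom", "start", "end"])
        assert intergenic_ratio(frags, IntervalSet({})) == 0.0

    def test_empty_fragments_error(self):
        with pytest.raises(ValueError):
            intergenic_ratio(pd.DataFrame(columns=["chrom", "start", "end"]),
                             IntervalSet({}))

    def test_agrees_with_per_fragment_scan(self, rng):
        members = [(int(s), int(s) + int(l)) for s, l in
                   zip(np.cumsum(rng.integers(200, 2000, 20)) * 3,
                       rng.integers(100, 1500, 20))]
        iset = IntervalSet({"c": members})
        starts = rng.integers(0, 120_000, 500)
        ends = starts + rng.integers(50, 600, 500)
        frags = pd.DataFrame({"chrom": "c", "start": starts, "end": ends})
        brute = np.mean([
            any(s <= qs and qe <= e for s, e in members)
            for qs, qe in zip(starts, ends)
        ])
        assert intergenic_ratio(frags, iset) == brute


class TestMetaprofile:
    def tile(self, chrom, start, end, frag_len):
        rows = [(chrom, s, min(s + frag_len, end)) for s in range(start, end, frag_len)]
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def test_uniform_coverage_is_flat(self):
        gene = GenomicInterval("c", 5_000, 10_000, name="g")
        frags = self.tile("c", 0, 20_000, 100)
        prof = metaprofile(frags, [gene], total_fragments=1_000_000)
        assert np.allclose(prof.values, prof.values[0])

    def test_body_only_fragments_leave_flanks_zero(self):
        gene = GenomicInterval("c", 5_000, 10_000, name="g")
        frags = self.tile("c", 5_000, 10_000, 100)
        prof = metaprofile(frags, [gene], total_fragments=10_000)
        assert np.all(prof.values[: prof.flank_bins] == 0)
        assert np.all(prof.values[-prof.flank_bins :] == 0)
        assert np.all(prof.body() > 0)

    def test_hand_computed_rpkm(self):
        # one 1000 bp gene tiled at depth 1 by ten 100 bp fragments, library
        # of 1e6 fragments: every body bin is depth 1 -> 1 * 1000 / 1 = 1000
        gene = GenomicInterval("c", 10_000, 11_000, name="g")
        frags = self.tile("c", 10_000, 11_000, 100)
        prof = metaprofile(frags, [gene], total_fragments=1_000_000)
        assert np.allclose(prof.body(), 1000.0)

    def test_short_gene_skipped(self):
        short = GenomicInterval("c", 100, 130, name="tiny")
        ok = GenomicInterval("c", 5_000, 10_000, name="g")
        frags = self.tile("c", 0, 20_000, 100)
        prof = metaprofile(frags, [short, ok], total_fragments=10_000)
        assert prof.n_genes == 1
        with pytest.raises(ValueError):
            metaprofile(frags, [short], total_fragments=10_000)

    def test_gene_body_density_matches_profile_scale(self):
        gene = GenomicInterval("c", 10_000, 11_000, name="g")
        frags = self.tile("c", 10_000, 11_000, 100)
        dens = gene_body_density(frags, [gene], total_fragments=1_000_000)
        assert np.isclose(dens["g"], 1000.0)


class TestSpearman:
    def test_monotone_pairs(self):
        x = pd.Series([1.0, 2, 3, 4, 5])
        assert spearman_deposition_vs_change(x, x * 3 + 1) == pytest.approx(1.0)
        assert spearman_deposition_vs_change(x, -x) == pytest.approx(-1.0)

    def test_tied_example_against_rank_formula(self):
        # x = 1..5 (ranks 1..5); y = (5,6,7,8,7) -> ranks (1,2,3.5,5,3.5);
        # Pearson on ranks = 8 / sqrt(10 * 9.5)
        x = pd.Series([1.0, 2, 3, 4, 5])
        y = pd.Series([5.0, 6, 7, 8, 7])
        expected = 8 / np.sqrt(10 * 9.5)
        assert np.isclose(spearman_deposition_vs_change(x, y), expected)

    def test_constant_vector_errors(self):
        x = pd.Series([1.0, 2, 3])
        with pytest.raises(ValueError):
            spearman_deposition_vs_change(x, pd.Series([2.0, 2, 2]))
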
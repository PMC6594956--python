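import math

import numpy as np
import pytest
from scipy import stats as ss

from keetools.enhancer_classifier import EnhancerCall, GeneEnhancerLabel
from keetools.genomic_io import GeneModel, GenomicInterval, SignalTrack
from keetools.integration_stats import (
    AtacPeakRecord,
    DERecord,
    atac_cross_tab,
    compare_expression,
    correlate_signal,
    de_by_class,
    fisher_exact,
    metaprofile,
    rank_sum,
)

from conftest import rank_sum_oracle


def iv(start, end, chrom="c"):
    return GenomicInterval(chrom, start, end)


class TestDERecord:
    @pytest.mark.parametrize(
        "log2fc, fdr, status",
        [(-1.2, 0.01, "down"), (0.8, 0.049, "up"), (-2.0, 0.05, "insensitive"),
         (0.0, 0.001, "insensitive"), (0.3, 0.9, "insensitive")],
    )
    def test_status_rule(self, log2fc, fdr, status):
        assert DERecord("g", log2fc, fdr).status == status


class TestAtacRecord:
    def test_direction_fdr_consistency_enforced(self):
        AtacPeakRecord(iv(0, 100), "decreased", 0.01)
        AtacPeakRecord(iv(0, 100), "unchanged", 0.5)
        with pytest.raises(ValueError):
            AtacPeakRecord(iv(0, 100), "decreased", 0.5)
        with pytest.raises(ValueError):
            AtacPeakRecord(iv(0, 100), "unchanged", 0.01)


class TestFisher:
    def test_symmetric_table(self):
        odds, p = fisher_exact([[5, 5], [5, 5]])
        assert odds == 1.0 and p == 1.0

    def test_known_table(self):
        odds, p = fisher_exact([[8, 2], [1, 5]])
        assert p == pytest.approx(0.034965034965, abs=1e-9)
        assert odds == pytest.approx(20.0)

    def test_extreme_antidiagonal_closed_form(self):
        for n in (2, 3, 5):
            odds, p = fisher_exact([[0, n], [n, 0]])
            assert odds == 0.0
            assert p == pytest.approx(min(1.0, 2 / math.comb(2 * n, n)), abs=1e-12)

    def test_infinite_and_nan_odds(self):
        assert math.isinf(fisher_exact([[3, 0], [1, 4]])[0])
        assert math.isnan(fisher_exact([[0, 0], [0, 5]])[0])

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [2, 3]])

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            t = rng.integers(0, 15, size=(2, 2))
            _, mine = fisher_exact(t)
            _, ref = ss.fisher_exact(t)
            assert mine == pytest.approx(ref, abs=1e-10)


class TestRankSum:
    def test_exact_matches_enumeration_small_groups(self):
        rng = np.random.default_rng(23)
        for _ in range(15):
            n1 = int(rng.integers(2, 7))
            n2 = int(rng.integers(2, 7))
            x = rng.integers(0, 8, n1).astype(float)  # integer values force ties
            y = rng.integers(0, 8, n2).astype(float)
            assert rank_sum(x, y) == pytest.approx(rank_sum_oracle(x, y), abs=1e-12)

    def test_exact_groups_3_4_all_assignments(self):
        x = [1.0, 5.0, 9.0]
        y = [2.0, 3.0, 7.0, 8.0]
        assert rank_sum(x, y) == pytest.approx(rank_sum_oracle(x, y), abs=1e-12)

    def test_matches_scipy_asymptotic_large(self):
        rng = np.random.default_rng(29)
        x = rng.normal(0, 1, 80)
        y = rng.normal(0.4, 1, 90)
        mine = rank_sum(x, y)
        ref = ss.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert mine == pytest.approx(ref, rel=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum([], [1.0])


class TestCorrelateSignal:
    def tracks(self, seed=0, n=50):
        rng = np.random.default_rng(seed)
        a = rng.poisson(30, n).astype(float)
        return SignalTrack(200, {"c": a}), a

    def test_identical_tracks_r1(self):
        ta, _ = self.tracks()
        ivs = [iv(i * 1000, i * 1000 + 600) for i in range(8)]
        _, r = correlate_signal(ta, ta, ivs)
        assert r == pytest.approx(1.0)

    def test_negated_track_raw_rm1(self):
        ta, a = self.tracks()
        tb = SignalTrack(200, {"c": -a})
        ivs = [iv(i * 1000, i * 1000 + 600) for i in range(8)]
        _, r = correlate_signal(ta, tb, ivs, transform="raw")
        assert r == pytest.approx(-1.0)

    def test_partial_bin_prorating(self):
        t = SignalTrack(200, {"c": np.array([10.0, 20.0])})
        df, _ = correlate_signal(
            t, t, [iv(0, 100), iv(100, 300), iv(0, 400)], transform="raw"
        )
        # [100,300): half of bin0 (5) + half of bin1 (10)
        assert df["signal_a"].tolist() == pytest.approx([5.0, 15.0, 30.0])

    def test_too_few_intervals_rejected(self):
        ta, _ = self.tracks()
        with pytest.raises(ValueError):
            correlate_signal(ta, ta, [iv(0, 200), iv(400, 600)])

    def test_latent_correlation_recovered(self):
        """Tracks generated with latent mark correlation 0.95 at 5000
        enhancers are recovered by log2(x+1) Pearson within +/- 0.02."""
        from keetools.synthetic_data import (
            SimConfig,
            simulate_enhancers_and_peaks,
            simulate_genome_and_genes,
            simulate_tracks,
        )

        cfg = SimConfig(
            seed=3, n_chroms=4, chrom_length_bp=10_000_000, n_genes=200,
            n_kee=2500, n_nonkee=2500, frac_intragenic=0.0,
        )
        sizes, genes = simulate_genome_and_genes(cfg)
        _, truths = simulate_enhancers_and_peaks(cfg, sizes, genes)
        ta, tb = simulate_tracks(cfg, truths, sizes)
        _, r = correlate_signal(ta, tb, [t.interval for t in truths])
        assert r == pytest.approx(0.95, abs=0.02)


class TestCompareExpression:
    def labels(self, n=20):
        return (
            [GeneEnhancerLabel(f"K{i}", "KEE_gene", True) for i in range(n)]
            + [GeneEnhancerLabel(f"N{i}", "nonKEE_gene", True) for i in range(n)]
        )

    def test_constant_shift_detected(self):
        rng = np.random.default_rng(31)
        base = rng.normal(0, 1, 20)
        expr = {f"K{i}": base[i] + 10 for i in range(20)}
        expr |= {f"N{i}": base[i] for i in range(20)}
        res = compare_expression(self.labels(), expr)
        assert res["kee_median"] - res["nonkee_median"] == pytest.approx(10)
        assert res["p"] < 0.01

    def test_h3k79_restriction_drops_unmarked(self):
        labels = self.labels()
        labels += [GeneEnhancerLabel("U1", "KEE_gene", False)]
        expr = {l.gene_id: 1.0 + i for i, l in enumerate(labels)}
        res = compare_expression(labels, expr, restrict_to_h3k79_marked=True)
        assert len(res["kee_values"]) == 20  # U1 excluded

    def test_empty_group_error(self):
        labels = [GeneEnhancerLabel("K1", "KEE_gene", True)]
        with pytest.raises(ValueError):
            compare_expression(labels, {"K1": 1.0})


class TestDeByClass:
    def make_labels(self, n_kee, n_non):
        return (
            [GeneEnhancerLabel(f"K{i}", "KEE_gene", True) for i in range(n_kee)]
            + [GeneEnhancerLabel(f"N{i}", "nonKEE_gene", True) for i in range(n_non)]
        )

    def test_counts_and_proportions(self):
        labels = self.make_labels(10, 5)
        recs = [DERecord(f"K{i}", -1.0, 0.01) for i in range(4)]
        recs += [DERecord(f"K{i}", 0.0, 0.5) for i in range(4, 10)]
        recs += [DERecord(f"N{i}", 1.0, 0.01) for i in range(5)]
        res = de_by_class(labels, recs)
        assert res["proportions"]["KEE_gene"]["down"] == pytest.approx(0.4)
        assert res["proportions"]["nonKEE_gene"]["up"] == pytest.approx(1.0)
        assert sum(res["proportions"]["KEE_gene"].values()) == pytest.approx(1.0)

    def test_no_down_genes_p_one(self):
        labels = self.make_labels(5, 5)
        recs = [DERecord(l.gene_id, 0.0, 0.9) for l in labels]
        res = de_by_class(labels, recs)
        assert res["collapsed"].cells[:, 0].tolist() == [0, 0]
        assert res["p"] == 1.0

    def test_duplicate_gene_rejected(self):
        labels = self.make_labels(2, 0)
        recs = [DERecord("K0", -1, 0.01), DERecord("K0", -1, 0.01)]
        with pytest.raises(ValueError, match="duplicate"):
            de_by_class(labels, recs)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(37)
        labels = self.make_labels(50, 50)
        recs = [
            DERecord(l.gene_id, float(rng.normal()), float(rng.random()))
            for l in labels
        ]
        res1 = de_by_class(labels, recs)
        perm = rng.permutation(len(recs))
        res2 = de_by_class(
            [labels[i] for i in rng.permutation(len(labels))],
            [recs[i] for i in perm],
        )
        assert np.array_equal(res1["table"].cells, res2["table"].cells)
        assert res1["p"] == res2["p"]

    def test_generator_proportions_recovered(self):
        """p_down 0.33 (KEE) / 0.20 (non-KEE) at n = 2000/1400 is recovered
        within +/- 0.03 with a significant collapsed Fisher test."""
        from keetools.synthetic_data import SimConfig, simulate_de_table

        label_map = {f"K{i}": "KEE_gene" for i in range(2000)}
        label_map |= {f"N{i}": "nonKEE_gene" for i in range(1400)}
        df, _ = simulate_de_table(SimConfig(seed=5), label_map)
        labels = [GeneEnhancerLabel(g, l, True) for g, l in label_map.items()]
        recs = [DERecord(r.gene_id, r.log2fc, r.fdr) for r in df.itertuples()]
        res = de_by_class(labels, recs)
        assert res["proportions"]["KEE_gene"]["down"] == pytest.approx(0.33, abs=0.03)
        assert res["proportions"]["nonKEE_gene"]["down"] == pytest.approx(0.20, abs=0.03)
        assert res["p"] < 0.05
        assert res["mean_log2fc"]["KEE_gene"] < res["mean_log2fc"]["nonKEE_gene"]


class TestAtacCrossTab:
    def setup_objects(self):
        enhancers = [
            EnhancerCall(interval=iv(1000, 2000), klass="KEE", gene_id="g1"),
            EnhancerCall(interval=iv(1800, 2600), klass="nonKEE", gene_id="g1"),
            EnhancerCall(interval=iv(5000, 6000), klass="nonKEE", gene_id="g2"),
        ]
        labels = [
            GeneEnhancerLabel("g1", "KEE_gene", True),
            GeneEnhancerLabel("g2", "nonKEE_gene", True),
        ]
        de = [DERecord("g1", -1.0, 0.01), DERecord("g2", 0.1, 0.8)]
        return enhancers, labels, de

    def test_kee_precedence_on_double_overlap(self):
        enhancers, labels, de = self.setup_objects()
        atac = [AtacPeakRecord(iv(1900, 2000), "decreased", 0.01)]  # overlaps both
        res = atac_cross_tab(atac, enhancers, labels, de)
        assert res["direction_table"].to_frame().loc["decreased", "KEE"] == 1
        assert res["decreased_table"].to_frame().loc["KEE", "down"] == 1

    def test_all_kee_down_proportion_one(self):
        enhancers, labels, de = self.setup_objects()
        atac = [
            AtacPeakRecord(iv(1100, 1300), "decreased", 0.01),
            AtacPeakRecord(iv(1400, 1600), "decreased", 0.02),
        ]
        res = atac_cross_tab(atac, enhancers, labels, de)
        assert res["down_proportions"]["KEE"] == 1.0

    def test_outside_enhancer_is_neither(self):
        enhancers, labels, de = self.setup_objects()
        atac = [AtacPeakRecord(iv(9000, 9100), "increased", 0.01)]
        res = atac_cross_tab(atac, enhancers, labels, de)
        assert res["direction_table"].to_frame().loc["increased", "neither"] == 1

    def test_generator_concordance_recovered(self):
        """Planted 0.73 / 0.21 down-gene concordance of decreased ATAC peaks
        at KEEs vs non-KEEs (200 each) is recovered within +/- 0.07."""
        from keetools.synthetic_data import (
            SimConfig,
            simulate_atac_table,
            simulate_de_table,
            simulate_enhancers_and_peaks,
            simulate_genome_and_genes,
            true_gene_labels,
        )

        cfg = SimConfig(seed=19)
        sizes, genes = simulate_genome_and_genes(cfg)
        _, truths = simulate_enhancers_and_peaks(cfg, sizes, genes)
        label_map = true_gene_labels(truths, genes)
        de_df, de_status = simulate_de_table(cfg, label_map)
        atac_df = simulate_atac_table(cfg, truths, de_status)
        atac = [
            AtacPeakRecord(
                GenomicInterval(r.chrom, int(r.start), int(r.end)),
                r.direction,
                r.fdr,
            )
            for r in atac_df.itertuples()
        ]
        enhancers = [
            EnhancerCall(interval=t.interval, klass=t.klass, gene_id=t.gene_id)
            for t in truths
        ]
        labels = [GeneEnhancerLabel(g, l, True) for g, l in label_map.items()]
        recs = [DERecord(r.gene_id, r.log2fc, r.fdr) for r in de_df.itertuples()]
        res = atac_cross_tab(atac, enhancers, labels, recs)
        assert res["down_proportions"]["KEE"] == pytest.approx(0.73, abs=0.07)
        assert res["down_proportions"]["nonKEE"] == pytest.approx(0.21, abs=0.07)
        assert res["p"] < 0.05


class TestMetaprofile:
    def test_constant_track_flat_profile(self):
        t = SignalTrack(100, {"c": np.full(100, 7.0)})
        profile, skipped = metaprofile(
            t, [iv(2000, 3000), iv(5000, 5600)], flank_bp=400, n_body_bins=10,
            n_flank_bins=4,
        )
        assert profile == pytest.approx(np.full(18, 7.0))
        assert skipped == 0

    def test_single_bin_body(self):
        arr = np.zeros(50)
        arr[10] = 5.0
        t = SignalTrack(100, {"c": arr})
        profile, _ = metaprofile(
            t, [iv(1000, 1100)], flank_bp=0, n_body_bins=6, n_flank_bins=1
        )
        assert profile == pytest.approx(np.full(6, 5.0))

    def test_two_intervals_average(self):
        arr = np.zeros(100)
        arr[10:20] = 2.0
        arr[50:60] = 4.0
        t = SignalTrack(100, {"c": arr})
        profile, _ = metaprofile(
            t, [iv(1000, 2000), iv(5000, 6000)], flank_bp=0, n_body_bins=5,
            n_flank_bins=1,
        )
        assert profile == pytest.approx(np.full(5, 3.0))

    def test_short_interval_skipped_with_count(self):
        t = SignalTrack(100, {"c": np.full(100, 1.0)})
        profile, skipped = metaprofile(
            t, [iv(0, 50), iv(1000, 2000)], flank_bp=0, n_body_bins=4, n_flank_bins=1
        )
        assert skipped == 1

    def test_kee_enrichment_separates_classes(self, default_sim):
        """On tracks with enhancer signal only at KEEs, the mean KEE body
        profile exceeds the non-KEE profile at every body bin."""
        from keetools.synthetic_data import simulate_tracks

        cfg, sizes, _, _, truths = default_sim
        track, _ = simulate_tracks(cfg, truths, sizes, kee_only=True)
        kee_iv = [t.interval for t in truths if t.klass == "KEE"]
        non_iv = [t.interval for t in truths if t.klass == "nonKEE"]
        pk, _ = metaprofile(track, kee_iv, flank_bp=2000, n_body_bins=20, n_flank_bins=10)
        pn, _ = metaprofile(track, non_iv, flank_bp=2000, n_body_bins=20, n_flank_bins=10)
        body = slice(10, 30)
        assert np.all(pk[body] > pn[body])
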
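import numpy as np
import pandas as pd
import pytest

from chromscore.enrichment import (
    EnrichmentError,
    cumulative_enrichment_curve,
    overlap_fold_enrichment,
    peak_center_enrichment,
    positional_enrichment,
    quantile_fold_enrichment,
)
from chromscore.genome_io import GenomeLayout, IntervalSet
from chromscore.scorehmm import Segmentation
from chromscore.tracks import ScoreTrack


def _segmentation(states_per_bin, K, bin_size=25, cell="CT1"):
    layout = GenomeLayout(("chr1",), (len(states_per_bin) * bin_size,), bin_size)
    return Segmentation(cell, layout, {"chr1": np.asarray(states_per_bin, dtype=int)}, K)


def _random_segmentation(n_bins, K, seed):
    rng = np.random.default_rng(seed)
    return _segmentation(rng.integers(1, K + 1, size=n_bins), K)


class TestOverlapFold:
    def test_hand_arithmetic(self):
        # genome 1000 bases (40 bins); state 2 covers bins 0-3 (100 bases);
        # annotation covers 50 bases, 20 of them inside state 2
        states = np.ones(40, dtype=int)
        states[:4] = 2
        seg = _segmentation(states, K=2)
        anno = IntervalSet.from_arrays(["chr1", "chr1"], [80, 200], [100, 230])
        out = overlap_fold_enrichment(seg, anno)
        fold = out[out["state"] == "E2"]["fold"].iloc[0]
        assert fold == pytest.approx((20 / 100) / (50 / 1000), abs=1e-9)

    def test_whole_genome_annotation_gives_unit_folds(self):
        seg = _random_segmentation(200, K=4, seed=0)
        anno = IntervalSet.from_arrays(["chr1"], [0], [200 * 25])
        out = overlap_fold_enrichment(seg, anno)
        np.testing.assert_allclose(out["fold"].dropna(), 1.0, atol=1e-9)

    def test_matches_base_by_base_counter(self):
        rng = np.random.default_rng(1)
        seg = _random_segmentation(400, K=3, seed=2)  # 10-kb toy genome
        starts = np.sort(rng.choice(9_500, size=20, replace=False))
        anno = IntervalSet.from_arrays(["chr1"] * 20, starts, starts + rng.integers(10, 400, 20))
        out = overlap_fold_enrichment(seg, anno)
        # oracle: exhaustive per-base counting
        spb = seg.state_per_base("chr1")
        mask = anno.coverage_mask("chr1", 10_000)
        for k in (1, 2, 3):
            in_state = spb == k
            expected = (mask[in_state].mean()) / mask.mean()
            got = out[out["state"] == f"E{k}"]["fold"].iloc[0]
            assert got == pytest.approx(expected, abs=1e-9)

    def test_conservation_of_weighted_folds(self):
        seg = _random_segmentation(500, K=5, seed=3)
        rng = np.random.default_rng(4)
        starts = np.sort(rng.choice(12_000, 15, replace=False))
        anno = IntervalSet.from_arrays(["chr1"] * 15, starts, starts + 50)
        out = overlap_fold_enrichment(seg, anno)
        weighted = (out["genome_pct"] / 100 * out["fold"]).sum()
        assert weighted == pytest.approx(1.0, abs=1e-9)

    def test_empty_state_reports_missing(self):
        seg = _segmentation(np.ones(40, dtype=int), K=2)
        anno = IntervalSet.from_arrays(["chr1"], [0], [100])
        out = overlap_fold_enrichment(seg, anno)
        assert np.isnan(out[out["state"] == "E2"]["fold"].iloc[0])


class TestPeakCenters:
    def test_single_point_formula(self):
        states = np.ones(40, dtype=int)
        states[10] = 2  # state 2 covers bases 250..275
        seg = _segmentation(states, K=2)
        peaks = IntervalSet.from_arrays(["chr1"], [250], [270])  # center 260 in state 2
        out = peak_center_enrichment(seg, peaks)
        fold = out[out["state"] == "E2"]["fold"].iloc[0]
        assert fold == pytest.approx(1000 / 25, abs=1e-9)  # genome/state bases

    def test_multicount_ratio_invariance(self):
        seg = _random_segmentation(100, K=2, seed=5)
        one = IntervalSet.from_arrays(["chr1"], [500], [600])
        two = IntervalSet.from_arrays(["chr1", "chr1"], [500, 500], [600, 600])
        f1 = peak_center_enrichment(seg, one, multicount=True)
        f2 = peak_center_enrichment(seg, two, multicount=True)
        pd.testing.assert_series_equal(f1["fold"], f2["fold"])
        assert f2["centers"].sum() == 2

    def test_matches_brute_force_on_random_peaks(self):
        rng = np.random.default_rng(6)
        seg = _random_segmentation(400, K=3, seed=7)
        starts = rng.integers(0, 9_800, size=20)
        peaks = IntervalSet.from_arrays(["chr1"] * 20, starts, starts + rng.integers(5, 200, 20))
        out = peak_center_enrichment(seg, peaks)
        spb = seg.state_per_base("chr1")
        centers = [s + (e - s) // 2 for s, e in zip(peaks.records["start"], peaks.records["end"])]
        counts = np.bincount(spb[np.array(centers)], minlength=4)
        for k in (1, 2, 3):
            expected = (counts[k] / 20) / ((spb == k).sum() / 10_000)
            got = out[out["state"] == f"E{k}"]["fold"].iloc[0]
            assert got == pytest.approx(expected, abs=1e-9)


class TestCumulativeCurve:
    def test_single_state_curve(self):
        seg = _segmentation(np.ones(40, dtype=int), K=1)
        peaks = IntervalSet.from_arrays(["chr1"], [100], [200])
        curve = cumulative_enrichment_curve(peak_center_enrichment(seg, peaks))
        assert len(curve) == 1
        assert curve["cum_genome_pct"].iloc[0] == pytest.approx(100.0)
        assert curve["cum_fold"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_last_point_is_always_unit_fold(self):
        rng = np.random.default_rng(8)
        seg = _random_segmentation(300, K=4, seed=9)
        starts = rng.integers(0, 7_400, size=30)
        peaks = IntervalSet.from_arrays(["chr1"] * 30, starts, starts + 20)
        curve = cumulative_enrichment_curve(peak_center_enrichment(seg, peaks))
        assert curve["cum_fold"].iloc[-1] == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(curve["cum_fold"]) <= 1e-9)  # non-increasing

    def test_three_state_hand_computation(self):
        table = pd.DataFrame(
            {"state": ["E1", "E2", "E3"], "genome_pct": [10.0, 30.0, 60.0],
             "fold": [5.0, 1.0, 0.333333333333]}
        )
        curve = cumulative_enrichment_curve(table)
        # sorted by fold: E1 then E2 then E3
        np.testing.assert_allclose(curve["cum_genome_pct"], [10, 40, 100])
        np.testing.assert_allclose(
            curve["cum_fold"],
            [5.0, (50 + 30) / 40, (50 + 30 + 20) / 100],
            atol=1e-6,
        )


class TestPositional:
    def test_null_distribution_gives_unit_folds(self):
        seg = _random_segmentation(2000, K=2, seed=10)
        rng = np.random.default_rng(11)
        pos = rng.integers(15_000, 35_000, size=200)
        anchors = IntervalSet.from_arrays(
            ["chr1"] * 200, pos, pos + 1, strands=rng.choice(["+", "-"], 200)
        )
        out = positional_enrichment(seg, anchors, half_window=2_000, step=500)
        assert out["fold"].between(0.5, 1.6).all()

    def test_negative_strand_mirrors_offsets(self):
        states = np.ones(400, dtype=int)
        states[180:200] = 2  # bases 4500..5000 in state 2
        seg = _segmentation(states, K=2)
        anchors = IntervalSet.from_arrays(["chr1"], [5200], [5201], strands=["-"])
        out = positional_enrichment(seg, anchors, half_window=1_000, step=500)
        # offset +500 on a negative-strand anchor reads base 4700 (state 2)
        row = out[(out["offset"] == 500) & (out["state"] == "E2")]
        assert row["fold"].iloc[0] > 1
        row = out[(out["offset"] == -500) & (out["state"] == "E2")]  # base 5700, state 1
        assert row["fold"].iloc[0] == 0

    def test_matches_exhaustive_counting(self):
        seg = _random_segmentation(400, K=3, seed=12)
        rng = np.random.default_rng(13)
        pos = rng.integers(2_000, 8_000, size=50)
        strands = rng.choice(["+", "-"], 50)
        anchors = IntervalSet.from_arrays(["chr1"] * 50, pos, pos + 1, strands=strands)
        out = positional_enrichment(seg, anchors, half_window=1_000, step=200)
        spb = seg.state_per_base("chr1")
        anchor_df = anchors.records.sort_values(["chrom", "start", "end"])
        for off in (-1000, 0, 600):
            counts = np.zeros(4)
            for p, s in zip(anchor_df["start"], anchor_df["strand"]):
                q = p + off if s == "+" else p - off
                if 0 <= q < 10_000:
                    counts[spb[q]] += 1
            for k in (1, 2, 3):
                expected = (counts[k] / counts.sum()) / ((spb == k).mean())
                got = out[(out["offset"] == off) & (out["state"] == f"E{k}")]["fold"].iloc[0]
                assert got == pytest.approx(expected, abs=1e-9)

    def test_unstranded_anchors_rejected(self):
        seg = _random_segmentation(40, K=2, seed=14)
        anchors = IntervalSet.from_arrays(["chr1"], [100], [101])
        with pytest.raises(EnrichmentError):
            positional_enrichment(seg, anchors)


class TestQuantileFold:
    def _track(self, values):
        layout = GenomeLayout(("chr1",), (values.size * 25,), 25)
        return ScoreTrack("CT1", "ChromScore", layout, {"chr1": values})

    def test_whole_genome_set_gives_unit_folds(self):
        rng = np.random.default_rng(15)
        track = self._track(rng.random(1000))
        sets = {"all": IntervalSet.from_arrays(["chr1"], [0], [25_000])}
        out = quantile_fold_enrichment(track, sets, n_quantiles=10, n_sample=5_000, seed=16)
        np.testing.assert_allclose(out["fold"].dropna(), 1.0)

    def test_elements_at_top_scores_enrich_top_quantile_only(self):
        values = np.linspace(0, 1, 1000)
        track = self._track(values)
        top = IntervalSet.from_arrays(["chr1"], [990 * 25], [1000 * 25])
        out = quantile_fold_enrichment(
            track, {"top": top}, n_quantiles=10, n_sample=8_000, seed=17
        )
        folds = out.set_index("quantile")["fold"]
        assert folds.iloc[-1] > 5
        np.testing.assert_allclose(folds.iloc[:9], 0.0)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(18)
        track = self._track(rng.random(2000))
        starts = np.sort(rng.choice(49_000, 30, replace=False))
        elems = IntervalSet.from_arrays(["chr1"] * 30, starts, starts + 500)
        n_quant, n_samp = 20, 10_000
        out = quantile_fold_enrichment(
            track, {"e": elems}, n_quantiles=n_quant, n_sample=n_samp, seed=19
        )
        # oracle: recompute folds from the same sampled positions
        from chromscore.tracks import sample_genome_positions

        ci, pos = sample_genome_positions(track.layout, n_samp, None, np.random.default_rng(19))
        scores = track.bin_values_at("chr1", pos)
        member = elems.coverage_mask("chr1", 50_000)[pos]
        order = np.argsort(scores, kind="stable")
        srt = scores[order]
        firsts = np.searchsorted(srt, scores, side="left")
        quant = np.minimum((firsts / (n_samp - 1) * n_quant).astype(int), n_quant - 1)
        for q in range(n_quant):
            sel = quant == q
            expected = member[sel].mean() / member.mean() if sel.any() else np.nan
            got = out[out["quantile"] == q]["fold"].iloc[0]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-9)

    def test_empty_element_set_warns_and_zeroes(self):
        track = self._track(np.random.default_rng(20).random(100))
        empty = IntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]))
        with pytest.warns(UserWarning, match="never sampled"):
            out = quantile_fold_enrichment(track, {"none": empty}, n_quantiles=5, n_sample=500, seed=21)
        assert (out["fold"].dropna() == 0).all()
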
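import numpy as np
import pytest
from scipy import stats

from chromscore.experts import ExpertConfig, ExpertEnsemble
from chromscore.features import assemble_features
from chromscore.genome_io import GenomeLayout, IntervalSet
from chromscore.tracks import (
    QuantileMap,
    ScoreTrack,
    TrackError,
    bin_centers,
    build_quantile_map,
    chromscore,
    normalize_scores,
    normalized_chromscore,
    pairwise_track_correlation,
    sample_genome_positions,
    score_genome,
    write_score_bedgraph,
)


def _track(values, cell="CT1", source="e", bin_size=25):
    values = {c: np.asarray(v, dtype=float) for c, v in values.items()}
    layout = GenomeLayout(tuple(values), tuple(v.size * bin_size for v in values.values()), bin_size)
    return ScoreTrack(cell, source, layout, values)


class TestScoreGenome:
    def test_bin_count_and_center_convention(self):
        layout = GenomeLayout(("chr1",), (1000,), 25)
        centers = bin_centers(layout, "chr1")
        assert centers.size == 40
        assert centers[0] == 12 and centers[1] == 37  # 13th nucleotide, 0-based

    def test_genomewide_scores_cover_every_bin(self, small_cfg, small_cell_inputs, trained_expert):
        ens, tf, _ = trained_expert
        track = score_genome(ens, small_cell_inputs["CT1"], tf)
        for chrom in small_cfg.layout.chrom_names:
            assert track.data[chrom].size == small_cfg.layout.n_bins(chrom)
            assert np.all((track.data[chrom] >= 0) & (track.data[chrom] <= 1))

    def test_bin_scores_match_manual_feature_assembly(self, small_cell_inputs, trained_expert):
        from chromscore.experts import predict_expert

        ens, tf, _ = trained_expert
        cell = small_cell_inputs["CT1"]
        track = score_genome(ens, cell, tf)
        for b in (100, 2500, 7000):
            ref = b * 25 + 12
            X = assemble_features(["chr1"], [ref], cell, tf)
            assert track.data["chr1"][b] == pytest.approx(predict_expert(ens, X)[0], abs=1e-12)

    def test_missing_mark_is_named(self, small_cell_inputs, trained_expert):
        ens, tf, _ = trained_expert
        cell = small_cell_inputs["CT1"]
        crippled = type(cell)(
            cell.cell_type, cell.layout,
            {k: v for k, v in cell.signals.items() if k != "DNase"},
            cell.peaks, cell.states,
        )
        with pytest.raises(TrackError, match="DNase"):
            score_genome(ens, crippled, tf)


class TestChromScore:
    def test_elementwise_mean(self):
        tracks = [_track({"chr1": [v] * 4}, source=f"e{i}") for i, v in enumerate([0.2, 0.4, 0.6])]
        cs = chromscore(tracks)
        np.testing.assert_allclose(cs.data["chr1"], 0.4)

    def test_single_track_identity(self):
        t = _track({"chr1": np.linspace(0, 1, 10)})
        np.testing.assert_allclose(chromscore([t]).data["chr1"], t.data["chr1"])

    def test_mean_matches_brute_force_at_random_bins(self):
        rng = np.random.default_rng(0)
        tracks = [_track({"chr1": rng.random(400)}, source=f"e{i}") for i in range(5)]
        cs = chromscore(tracks)
        for b in rng.integers(0, 400, size=100):
            manual = np.mean([t.data["chr1"][b] for t in tracks])
            assert cs.data["chr1"][b] == pytest.approx(manual, abs=1e-12)

    def test_bounded_by_expert_extremes(self):
        rng = np.random.default_rng(1)
        tracks = [_track({"chr1": rng.random(200)}, source=f"e{i}") for i in range(4)]
        cs = chromscore(tracks).data["chr1"]
        stacked = np.stack([t.data["chr1"] for t in tracks])
        assert np.all(cs >= stacked.min(axis=0)) and np.all(cs <= stacked.max(axis=0))

    def test_layout_mismatch_rejected(self):
        with pytest.raises(TrackError):
            chromscore([_track({"chr1": [0.1] * 4}), _track({"chr1": [0.1] * 8})])


class TestQuantileNormalization:
    def _tracks(self, n_bins=4000, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.random(n_bins)
        return {
            "a": _track({"chr1": base}, source="a"),
            # a strictly monotone transform of the same scores
            "b": _track({"chr1": base**3}, source="b"),
        }

    def test_identical_distributions_map_to_identity(self):
        rng = np.random.default_rng(1)
        vals = rng.random(4000)
        tracks = {
            "a": _track({"chr1": vals}, source="a"),
            "b": _track({"chr1": vals}, source="b"),
        }
        qmap = build_quantile_map(tracks, n_sample=20_000, n_bins=100, seed=2)
        na = normalize_scores(qmap, tracks["a"]).data["chr1"]
        assert np.abs(na - vals).max() < 0.02  # within bin resolution

    def test_monotone_transform_collapses_to_common_distribution(self):
        """Against a brute-force full-sort quantile normalization oracle."""
        tracks = self._tracks()
        qmap = build_quantile_map(tracks, n_sample=20_000, n_bins=200, seed=3)
        na = normalize_scores(qmap, tracks["a"]).data["chr1"]
        nb = normalize_scores(qmap, tracks["b"]).data["chr1"]
        # the two normalized tracks agree bin-for-bin (same underlying ranks)
        assert np.abs(na - nb).max() < 0.02
        # oracle: direct full-sort mapping of b's values onto a/b rank medians
        a = np.sort(tracks["a"].data["chr1"])
        b = np.sort(tracks["b"].data["chr1"])
        ref = np.median(np.stack([a, b]), axis=0)
        rank = np.searchsorted(b, tracks["b"].data["chr1"], side="right") - 1
        oracle = ref[np.clip(rank, 0, ref.size - 1)]
        assert np.abs(nb - oracle).max() < 0.02

    def test_normalized_scores_monotone_in_raw(self):
        tracks = self._tracks()
        qmap = build_quantile_map(tracks, n_sample=10_000, n_bins=100, seed=4)
        raw = tracks["b"].data["chr1"]
        norm = normalize_scores(qmap, tracks["b"]).data["chr1"]
        order = np.argsort(raw)
        assert np.all(np.diff(norm[order]) >= 0)
        # quantile binning introduces ties, so rank correlation is only
        # near-perfect, not exactly 1
        assert stats.spearmanr(raw, norm).statistic > 0.999

    def test_ks_distance_between_normalized_experts_within_bin_resolution(self):
        rng = np.random.default_rng(5)
        tracks = {
            "a": _track({"chr1": rng.beta(2, 5, 4000)}, source="a"),
            "b": _track({"chr1": rng.beta(5, 2, 4000)}, source="b"),
        }
        n_bins = 100
        qmap = build_quantile_map(tracks, n_sample=20_000, n_bins=n_bins, seed=6)
        na = normalize_scores(qmap, tracks["a"]).data["chr1"]
        nb = normalize_scores(qmap, tracks["b"]).data["chr1"]
        ks = stats.ks_2samp(na, nb).statistic
        assert ks <= 1.0 / n_bins + 0.01

    def test_constant_track_normalizes_to_constant(self):
        tracks = self._tracks()
        qmap = build_quantile_map(tracks, n_sample=5_000, n_bins=50, seed=7)
        const = _track({"chr1": np.full(100, 0.5)}, source="a")
        out = normalize_scores(qmap, const).data["chr1"]
        assert np.unique(out).size == 1

    def test_maximum_maps_to_top_reference_bin(self):
        tracks = self._tracks()
        qmap = build_quantile_map(tracks, n_sample=10_000, n_bins=100, seed=8)
        top_raw = tracks["a"].data["chr1"].max()
        got = qmap.normalize_values("a", np.array([top_raw, top_raw + 10]))
        assert got[0] == qmap.bin_values["a"][-1]
        assert got[1] == qmap.bin_values["a"][-1]  # out-of-range clamps

    def test_unknown_expert_rejected(self):
        tracks = self._tracks()
        qmap = build_quantile_map(tracks, n_sample=5_000, n_bins=50, seed=9)
        with pytest.raises(TrackError):
            qmap.normalize_values("zzz", np.array([0.5]))

    def test_normalized_chromscore_is_mean_of_normalized(self):
        tracks = self._tracks()
        qmap = build_quantile_map(tracks, n_sample=5_000, n_bins=50, seed=10)
        ncs = normalized_chromscore(qmap, tracks)
        manual = np.mean(
            [normalize_scores(qmap, t).data["chr1"] for t in tracks.values()], axis=0
        )
        np.testing.assert_allclose(ncs.data["chr1"], manual)


class TestPairwiseCorrelation:
    def test_self_and_inverted(self):
        rng = np.random.default_rng(0)
        vals = rng.random(2000)
        tracks = {
            "a": _track({"chr1": vals}, source="a"),
            "b": _track({"chr1": 1 - vals}, source="b"),
        }
        names, corr = pairwise_track_correlation(tracks, n_sample=5_000, seed=1)
        i, j = names.index("a"), names.index("b")
        assert corr[i, i] == pytest.approx(1.0)
        assert corr[i, j] == pytest.approx(-1.0)

    def test_sampled_correlation_matches_exhaustive(self):
        rng = np.random.default_rng(2)
        x = rng.random(20_000)
        y = 0.6 * x + 0.4 * rng.random(20_000)
        tracks = {
            "a": _track({"chr1": x}, source="a"),
            "b": _track({"chr1": y}, source="b"),
        }
        names, corr = pairwise_track_correlation(tracks, n_sample=100_000, seed=3)
        exhaustive = np.corrcoef(np.repeat(x, 25), np.repeat(y, 25))[0, 1]
        assert abs(corr[0, 1] - exhaustive) < 0.02

    def test_zero_variance_track_reports_missing(self):
        tracks = {
            "a": _track({"chr1": np.full(100, 0.3)}, source="a"),
            "b": _track({"chr1": np.random.default_rng(4).random(100)}, source="b"),
        }
        _, corr = pairwise_track_correlation(tracks, n_sample=1_000, seed=5)
        assert np.isnan(corr[0, 1]) and np.isnan(corr[0, 0])

    def test_blacklist_positions_never_sampled(self):
        layout = GenomeLayout(("chr1",), (10_000,), 25)
        bl = IntervalSet.from_arrays(["chr1"], [0], [9_000])
        rng = np.random.default_rng(6)
        ci, pos = sample_genome_positions(layout, 500, bl, rng)
        assert np.all(pos >= 9_000)


def test_score_bedgraph_round_trip(tmp_path):
    from chromscore.genome_io import read_signal_track

    rng = np.random.default_rng(7)
    track = _track({"chr1": rng.random(40)})
    p = tmp_path / "t.bedgraph"
    write_score_bedgraph(track, p)
    sig = read_signal_track(p, track.layout)
    np.testing.assert_allclose(sig.binned("chr1", 25), track.data["chr1"], atol=1e-6)
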
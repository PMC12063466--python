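import itertools

import numpy as np
import pytest

from chromscore.genome_io import BinarizedTracks, GenomeLayout
from chromscore.scorehmm import (
    HMMError,
    HMMParams,
    MULTI_EXPERT,
    NO_EXPERT,
    SINGLE_EXPERT,
    UNCLASSIFIED,
    binarize_top_fraction,
    decode_segmentation,
    hmm_loglik,
    learn_hmm,
    order_and_classify_states,
    posteriors,
    segmentation_to_bed,
)
from chromscore.tracks import ScoreTrack


def _track(values):
    layout = GenomeLayout(("chr1",), (len(values) * 25,), 25)
    return ScoreTrack("CT1", "e", layout, {"chr1": np.asarray(values, dtype=float)})


class TestBinarization:
    def test_distinct_scores_mark_exact_top_fraction(self):
        rng = np.random.default_rng(0)
        track = _track(rng.permutation(np.linspace(0, 1, 200)))
        ones = binarize_top_fraction(track, q=0.02)["chr1"]
        assert ones.sum() == 4  # floor(0.02 * 200)

    def test_all_ties_all_marked(self):
        track = _track(np.full(100, 0.7))
        ones = binarize_top_fraction(track, q=0.02)["chr1"]
        assert ones.sum() == 100  # >=-threshold policy on a degenerate track

    def test_continuous_scores_hit_two_percent_within_one_bin(self):
        rng = np.random.default_rng(1)
        n = 100_000
        track = _track(rng.random(n))
        ones = int(binarize_top_fraction(track, q=0.02)["chr1"].sum())
        assert abs(ones - 0.02 * n) <= 1

    def test_invalid_fraction_rejected(self):
        with pytest.raises(HMMError):
            binarize_top_fraction(_track([0.1]), q=0.0)

    def test_threshold_is_per_track(self):
        # two tracks with shifted distributions each mark their own top 2%
        rng = np.random.default_rng(2)
        low, high = _track(rng.random(1000) * 0.1), _track(rng.random(1000))
        assert binarize_top_fraction(low)["chr1"].sum() == binarize_top_fraction(high)["chr1"].sum() == 20


def _params(initial, transition, emission):
    return HMMParams(
        np.asarray(initial, float), np.asarray(transition, float),
        np.asarray(emission, float), tuple(f"e{i}" for i in range(np.shape(emission)[1])),
    )


class TestLikelihood:
    def test_single_state_closed_form(self):
        p = _params([1.0], [[1.0]], [[0.3, 0.8]])
        seq = np.array([[1, 0], [0, 1], [1, 1]])
        expected = (
            np.log(0.3) + np.log(0.2)
            + np.log(0.7) + np.log(0.8)
            + np.log(0.3) + np.log(0.8)
        )
        assert hmm_loglik(p, seq) == pytest.approx(expected, abs=1e-10)

    def test_matches_path_enumeration_on_short_sequences(self):
        """Forward recursion equals the brute-force sum over all state paths."""
        rng = np.random.default_rng(3)
        K, E, T = 2, 3, 3
        trans = rng.dirichlet(np.ones(K), size=K)
        init = rng.dirichlet(np.ones(K))
        emis = rng.uniform(0.1, 0.9, size=(K, E))
        p = _params(init, trans, emis)
        seq = rng.integers(0, 2, size=(T, E))
        total = 0.0
        for path in itertools.product(range(K), repeat=T):
            prob = init[path[0]]
            for t in range(1, T):
                prob *= trans[path[t - 1], path[t]]
            for t in range(T):
                for e in range(E):
                    prob *= emis[path[t], e] if seq[t, e] else 1 - emis[path[t], e]
            total += prob
        assert hmm_loglik(p, seq) == pytest.approx(np.log(total), abs=1e-10)

    def test_longer_sequence_never_more_likely(self):
        rng = np.random.default_rng(4)
        p = _params([0.5, 0.5], [[0.9, 0.1], [0.2, 0.8]], rng.uniform(0.2, 0.8, (2, 2)))
        seq = rng.integers(0, 2, size=(10, 2))
        longer = np.vstack([seq, rng.integers(0, 2, size=(1, 2))])
        assert hmm_loglik(p, longer) <= hmm_loglik(p, seq)

    def test_non_binary_observations_rejected(self):
        p = _params([1.0], [[1.0]], [[0.5]])
        with pytest.raises(HMMError):
            hmm_loglik(p, np.array([[2]]))


def _simulate_hmm(params: HMMParams, T: int, rng) -> tuple[np.ndarray, np.ndarray]:
    K, E = params.emission.shape
    states = np.empty(T, dtype=int)
    obs = np.empty((T, E), dtype=np.uint8)
    states[0] = rng.choice(K, p=params.initial)
    for t in range(1, T):
        states[t] = rng.choice(K, p=params.transition[states[t - 1]])
    for t in range(T):
        obs[t] = rng.random(E) < params.emission[states[t]]
    return states, obs


class TestLearning:
    def test_loglik_monotone_over_em_iterations(self):
        rng = np.random.default_rng(5)
        obs = rng.integers(0, 2, size=(2000, 3)).astype(np.uint8)
        b = BinarizedTracks("CT1", "chr1", ("a", "b", "c"), obs)
        _, trace = learn_hmm([b], K=3, seed=1, n_restarts=1, max_iter=30)
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-6 * np.abs(trace[:-1]))

    def test_k1_recovers_column_means(self):
        rng = np.random.default_rng(6)
        obs = (rng.random((5000, 2)) < [0.3, 0.7]).astype(np.uint8)
        b = BinarizedTracks("CT1", "chr1", ("a", "b"), obs)
        params, _ = learn_hmm([b], K=1, seed=0, n_restarts=1, max_iter=50)
        np.testing.assert_allclose(params.emission[0], obs.mean(axis=0), atol=1e-9)

    def test_two_state_parameter_recovery(self):
        """Emissions of a known 2-state generator recovered within 0.05."""
        truth = _params(
            [0.5, 0.5],
            [[0.95, 0.05], [0.10, 0.90]],
            [[0.9, 0.8, 0.1], [0.05, 0.1, 0.6]],
        )
        rng = np.random.default_rng(7)
        _, obs = _simulate_hmm(truth, 20_000, rng)
        b = BinarizedTracks("CT1", "chr1", truth.track_names, obs)
        params, _ = learn_hmm([b], K=2, seed=2, n_restarts=3, max_iter=100)
        # match learned states to generating states by emission distance
        d_direct = np.abs(params.emission - truth.emission).max()
        d_swapped = np.abs(params.emission[::-1] - truth.emission).max()
        assert min(d_direct, d_swapped) < 0.05

    def test_learned_loglik_is_self_consistent(self):
        rng = np.random.default_rng(8)
        obs = rng.integers(0, 2, size=(1000, 2)).astype(np.uint8)
        b = BinarizedTracks("CT1", "chr1", ("a", "b"), obs)
        params, trace = learn_hmm([b], K=2, seed=3, n_restarts=1, max_iter=40)
        assert hmm_loglik(params, obs) >= trace[-1] - 1e-6 * abs(trace[-1])

    def test_shared_parameters_across_sequences(self):
        rng = np.random.default_rng(9)
        truth = _params([0.5, 0.5], [[0.9, 0.1], [0.1, 0.9]], [[0.9, 0.1], [0.1, 0.9]])
        seqs = []
        for cell in ("CT1", "CT2"):
            for chrom in ("chr1", "chr2"):
                _, obs = _simulate_hmm(truth, 3000, rng)
                seqs.append(BinarizedTracks(cell, chrom, truth.track_names, obs))
        params, _ = learn_hmm(seqs, K=2, seed=4, n_restarts=2, max_iter=60)
        d = min(
            np.abs(params.emission - truth.emission).max(),
            np.abs(params.emission[::-1] - truth.emission).max(),
        )
        assert d < 0.05

    def test_track_name_mismatch_rejected(self):
        a = BinarizedTracks("c", "chr1", ("x",), np.zeros((5, 1), dtype=int))
        b = BinarizedTracks("c", "chr2", ("y",), np.zeros((5, 1), dtype=int))
        with pytest.raises(HMMError):
            learn_hmm([a, b], K=2)


class TestDecoding:
    def test_single_state_model_decodes_to_one(self):
        p = _params([1.0], [[1.0]], [[0.5, 0.5]])
        b = BinarizedTracks("CT1", "chr1", ("a", "b"), np.ones((10, 2), dtype=int))
        seg = decode_segmentation(p, [b])["CT1"]
        assert np.all(seg.states["chr1"] == 1)

    def test_posteriors_normalize(self):
        rng = np.random.default_rng(10)
        p = _params([0.4, 0.6], [[0.8, 0.2], [0.3, 0.7]], rng.uniform(0.2, 0.8, (2, 3)))
        seq = rng.integers(0, 2, size=(50, 3))
        g = posteriors(p, seq)
        np.testing.assert_allclose(g.sum(axis=1), 1.0, atol=1e-9)

    def test_near_deterministic_emissions_recover_generating_states(self):
        truth = _params(
            [0.5, 0.5],
            [[0.98, 0.02], [0.02, 0.98]],
            [[0.99, 0.99, 0.01], [0.01, 0.01, 0.99]],
        )
        rng = np.random.default_rng(11)
        states, obs = _simulate_hmm(truth, 5000, rng)
        b = BinarizedTracks("CT1", "chr1", truth.track_names, obs)
        seg = decode_segmentation(truth, [b])["CT1"]
        agreement = np.mean(seg.states["chr1"] - 1 == states)
        assert max(agreement, 1 - agreement) >= 0.99

    def test_segmentation_bed_round_trip_covers_genome(self, tmp_path):
        p = _params([0.5, 0.5], [[0.9, 0.1], [0.1, 0.9]], [[0.9, 0.1], [0.1, 0.9]])
        rng = np.random.default_rng(12)
        b = BinarizedTracks("CT1", "chr1", ("a", "b"), rng.integers(0, 2, (40, 2)))
        seg = decode_segmentation(p, [b])["CT1"]
        path = tmp_path / "seg.bed"
        segmentation_to_bed(seg, path)
        from chromscore.genome_io import read_intervals

        iv = read_intervals(path)
        assert iv.total_bases() == 40 * 25
        assert set(iv.records["name"]) <= {"E1", "E2"}


class TestStateClassification:
    def test_rules(self):
        emis = np.array(
            [
                [0.5, 0.6, 0.1],       # two experts >= 0.2 -> multi
                [0.95, 0.05, 0.0],     # one >= 0.9, rest < 0.1 -> single
                [0.0005, 0.0005, 0.0005],  # all < 0.001 -> none
                [0.5, 0.05, 0.05],     # one mid emission -> unclassified
            ]
        )
        K = emis.shape[0]
        p = _params(np.full(K, 1 / K), np.full((K, K), 1 / K), emis)
        order, classes = order_and_classify_states(p)
        by_original = {order[i]: classes[i] for i in range(K)}
        assert by_original[0] == MULTI_EXPERT
        assert by_original[1] == SINGLE_EXPERT
        assert by_original[2] == NO_EXPERT
        assert by_original[3] == UNCLASSIFIED

    def test_order_is_by_descending_mean_emission(self):
        emis = np.array([[0.1, 0.1], [0.9, 0.9], [0.5, 0.5]])
        p = _params(np.full(3, 1 / 3), np.full((3, 3), 1 / 3), emis)
        order, _ = order_and_classify_states(p)
        assert order.tolist() == [1, 2, 0]
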
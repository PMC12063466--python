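"""Multivariate Bernoulli HMM over binarized expert tracks.

Expert score tracks are binarized at a top-fraction threshold (default: the
top 2% of 25-bp bins per expert per cell type get a 1). A single hidden
Markov model with K states (default 15) is then learned across all cell
types jointly — the concatenated approach: every (cell, chromosome) pair is
one observation sequence and all sequences share the initial distribution,
transition matrix and emission parameters. Emissions are conditionally
independent Bernoullis per expert: emission[k, e] is the probability that
state k shows a top-scoring prediction for expert e. Decoding assigns each
bin its maximum-posterior state, and states are ordered by decreasing mean
emission and classified as multi-expert / single-expert / no-expert by
fixed emission-probability thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import BinarizedTracks, GenomeLayout, IntervalSet
from .tracks import ScoreTrack

DEFAULT_K = 15
DEFAULT_TOP_FRACTION = 0.02
EMISSION_CLAMP = 1e-6

MULTI_EXPERT = "multi_expert"
SINGLE_EXPERT = "single_expert"
NO_EXPERT = "no_expert"
UNCLASSIFIED = "unclassified"


class HMMError(ValueError):
    pass


@dataclass
class HMMParams:
    """Shared-state Bernoulli HMM parameters."""

    initial: np.ndarray      # (K,)
    transition: np.ndarray   # (K, K)
    emission: np.ndarray     # (K, E) Bernoulli success probabilities
    track_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=np.float64)
        self.transition = np.asarray(self.transition, dtype=np.float64)
        self.emission = np.asarray(self.emission, dtype=np.float64)
        K = self.initial.size
        if self.transition.shape != (K, K) or self.emission.shape[0] != K:
            raise HMMError("inconsistent parameter shapes")
        if abs(self.initial.sum() - 1) > 1e-9 or np.abs(self.transition.sum(1) - 1).max() > 1e-9:
            raise HMMError("initial distribution and transition rows must sum to 1")
        if ((self.emission < 0) | (self.emission > 1)).any():
            raise HMMError("emission probabilities must lie in [0, 1]")

    @property
    def K(self) -> int:
        return self.initial.size


@dataclass
class Segmentation:
    """Per-cell-type max-posterior state per 25-bp bin (labels 1..K)."""

    cell_type: str
    layout: GenomeLayout
    states: dict[str, np.ndarray]
    K: int
    state_order: np.ndarray | None = None  # permutation applied, if any

    def state_per_base(self, chrom: str) -> np.ndarray:
        arr = np.repeat(self.states[chrom], self.layout.bin_size)
        return arr[: self.layout.length_of(chrom)]

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.states[c] for c in self.layout.chrom_names])


def binarize_top_fraction(track: ScoreTrack, q: float = DEFAULT_TOP_FRACTION) -> dict[str, np.ndarray]:
    """Mark the top-fraction of 25-bp bins (by score, over the whole genome) as 1.

    The threshold is the score at ascending rank ceil((1-q)*N) (0-based), so
    with distinct scores exactly floor(q*N) bins are set; tied scores at the
    threshold are all included (>= policy).
    """
    if not 0 < q < 1:
        raise HMMError("q must lie strictly between 0 and 1")
    allv = track.concatenated()
    if allv.size == 0:
        raise HMMError("empty track")
    idx = int(np.ceil((1 - q) * allv.size))
    srt = np.sort(allv)
    threshold = srt[min(idx, allv.size - 1)]
    return {chrom: (arr >= threshold).astype(np.uint8) for chrom, arr in track.data.items()}


def binarize_cell(
    expert_tracks: dict[str, ScoreTrack],
    cell_type: str,
    q: float = DEFAULT_TOP_FRACTION,
) -> list[BinarizedTracks]:
    """Binarize all experts of one cell type into per-chromosome track sets."""
    names = tuple(sorted(expert_tracks))
    layout = expert_tracks[names[0]].layout
    per_expert = {n: binarize_top_fraction(expert_tracks[n], q) for n in names}
    out = []
    for chrom in layout.chrom_names:
        matrix = np.stack([per_expert[n][chrom] for n in names], axis=1)
        out.append(BinarizedTracks(cell_type, chrom, names, matrix))
    return out


def _log_emission_matrix(params: HMMParams, seq: np.ndarray) -> np.ndarray:
    """(T, K) log P(obs_t | state k), clamping emissions away from 0/1."""
    p = np.clip(params.emission, EMISSION_CLAMP, 1 - EMISSION_CLAMP)
    X = seq.astype(np.float64)
    return X @ np.log(p).T + (1 - X) @ np.log1p(-p).T


def _forward(params: HMMParams, logB: np.ndarray):
    """Scaled forward pass; returns (alpha, per-step scales, loglik)."""
    T, K = logB.shape
    B = np.exp(logB - logB.max(axis=1, keepdims=True))
    alpha = np.empty((T, K))
    scales = np.empty(T)
    a = params.initial * B[0]
    scales[0] = a.sum()
    alpha[0] = a / scales[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ params.transition) * B[t]
        scales[t] = a.sum()
        alpha[t] = a / scales[t]
    loglik = float(np.log(scales).sum() + logB.max(axis=1).sum())
    return alpha, scales, loglik


def _backward(params: HMMParams, logB: np.ndarray, scales: np.ndarray) -> np.ndarray:
    T, K = logB.shape
    B = np.exp(logB - logB.max(axis=1, keepdims=True))
    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (params.transition @ (B[t + 1] * beta[t + 1])) / scales[t + 1]
    return beta


def hmm_loglik(params: HMMParams, seq: np.ndarray) -> float:
    """Log-likelihood of a (T, E) binary sequence under the model (scaled forward)."""
    seq = np.asarray(seq)
    if not np.isin(seq, (0, 1)).all():
        raise HMMError("observations must be binary")
    _, _, ll = _forward(params, _log_emission_matrix(params, seq))
    return ll


def posteriors(params: HMMParams, seq: np.ndarray) -> np.ndarray:
    """(T, K) posterior state probabilities by forward-backward."""
    logB = _log_emission_matrix(params, np.asarray(seq))
    alpha, scales, _ = _forward(params, logB)
    beta = _backward(params, logB, scales)
    g = alpha * beta
    return g / g.sum(axis=1, keepdims=True)


def _init_params(K: int, E: int, track_names, rng: np.random.Generator) -> HMMParams:
    emission = rng.uniform(0.1, 0.9, size=(K, E))
    transition = np.full((K, K), 0.1 / max(K - 1, 1))
    np.fill_diagonal(transition, 0.9)
    if K == 1:
        transition = np.ones((1, 1))
    initial = np.full(K, 1.0 / K)
    return HMMParams(initial, transition, emission, tuple(track_names))


def learn_hmm(
    binarized: list[BinarizedTracks],
    K: int = DEFAULT_K,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> tuple[HMMParams, list[float]]:
    """Baum-Welch over all (cell, chromosome) sequences with shared parameters.

    Full-batch EM with seeded random restarts; returns the best restart's
    parameters and its per-iteration log-likelihood trace (monotone
    non-decreasing up to numerical tolerance).
    """
    if not binarized:
        raise HMMError("no training sequences")
    track_names = binarized[0].track_names
    if any(b.track_names != track_names for b in binarized):
        raise HMMError("all sequences must share track names")
    seqs = [b.matrix.astype(np.float64) for b in binarized]
    E = len(track_names)
    n_patterns = len({tuple(row) for s in seqs for row in s.astype(int)[: 10_000]})
    if K > n_patterns:
        import warnings

        warnings.warn(
            f"K={K} exceeds the {n_patterns} distinct observation patterns seen",
            stacklevel=2,
        )

    best: tuple[float, HMMParams, list[float]] | None = None
    for r in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(r,)))
        params = _init_params(K, E, track_names, rng)
        trace: list[float] = []
        prev_ll = -np.inf
        for _ in range(max_iter):
            ll_total = 0.0
            init_acc = np.zeros(K)
            trans_acc = np.zeros((K, K))
            emit_num = np.zeros((K, E))
            emit_den = np.zeros(K)
            p = np.clip(params.emission, EMISSION_CLAMP, 1 - EMISSION_CLAMP)
            for seq in seqs:
                logB = seq @ np.log(p).T + (1 - seq) @ np.log1p(-p).T
                alpha, scales, ll = _forward(params, logB)
                beta = _backward(params, logB, scales)
                gamma = alpha * beta
                gamma /= gamma.sum(axis=1, keepdims=True)
                B = np.exp(logB - logB.max(axis=1, keepdims=True))
                # xi_sum[i,j] = trans[i,j] * sum_t alpha[t,i] B[t+1,j] beta[t+1,j] / c[t+1]
                weighted = B[1:] * beta[1:] / scales[1:, None]
                xi_sum = params.transition * (alpha[:-1].T @ weighted)
                ll_total += ll
                init_acc += gamma[0]
                trans_acc += xi_sum
                emit_num += gamma.T @ seq
                emit_den += gamma.sum(axis=0)
            trace.append(ll_total)
            params = HMMParams(
                init_acc / init_acc.sum(),
                trans_acc / np.maximum(trans_acc.sum(axis=1, keepdims=True), 1e-300),
                np.clip(emit_num / np.maximum(emit_den[:, None], 1e-300), 0.0, 1.0),
                track_names,
            )
            if np.isfinite(prev_ll) and abs(ll_total - prev_ll) < tol * abs(prev_ll):
                prev_ll = ll_total
                break
            prev_ll = ll_total
        final_ll = sum(hmm_loglik(params, s) for s in seqs)
        if best is None or final_ll > best[0]:
            best = (final_ll, params, trace)
    return best[1], best[2]


def decode_segmentation(
    params: HMMParams,
    binarized: list[BinarizedTracks],
) -> dict[str, Segmentation]:
    """Max-posterior state per bin for each cell type (ties take the lowest state)."""
    by_cell: dict[str, dict[str, np.ndarray]] = {}
    layouts: dict[str, list[tuple[str, int]]] = {}
    for b in binarized:
        post = posteriors(params, b.matrix)
        states = post.argmax(axis=1) + 1  # argmax takes the lowest index on ties
        by_cell.setdefault(b.cell_type, {})[b.chrom] = states.astype(np.int32)
        layouts.setdefault(b.cell_type, []).append((b.chrom, b.matrix.shape[0]))
    out = {}
    for cell, chrom_states in by_cell.items():
        chroms = [c for c, _ in layouts[cell]]
        lengths = [n * 25 for _, n in layouts[cell]]
        layout = GenomeLayout(tuple(chroms), tuple(lengths), 25)
        out[cell] = Segmentation(cell, layout, chrom_states, params.K)
    return out


def order_and_classify_states(params: HMMParams) -> tuple[np.ndarray, list[str]]:
    """Order states by decreasing mean emission; classify each by emission pattern.

    multi-expert: at least two experts with emission >= 0.20.
    single-expert: exactly one expert >= 0.90 and all others < 0.10.
    no-expert: every expert < 0.001.
    Anything else is unclassified.
    """
    order = np.argsort(-params.emission.mean(axis=1), kind="stable")
    classes = []
    for k in order:
        row = params.emission[k]
        if (row < 0.001).all():
            classes.append(NO_EXPERT)
        elif (row >= 0.20).sum() >= 2:
            classes.append(MULTI_EXPERT)
        elif (row >= 0.90).sum() == 1 and (row[row < 0.90] < 0.10).all():
            classes.append(SINGLE_EXPERT)
        else:
            classes.append(UNCLASSIFIED)
    return order, classes


def segmentation_to_bed(seg: Segmentation, path) -> None:
    """Write a segmentation as BED with merged runs of equal state (labels E1..EK)."""
    with open(path, "w") as fh:
        for chrom in seg.layout.chrom_names:
            states = seg.states[chrom]
            length = seg.layout.length_of(chrom)
            change = np.flatnonzero(np.diff(states)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [states.size]))
            for s, e in zip(starts, ends):
                fh.write(
                    f"{chrom}\t{s * seg.layout.bin_size}\t{min(e * seg.layout.bin_size, length)}\tE{states[s]}\n"
                )


def segmentation_to_intervals(seg: Segmentation) -> IntervalSet:
    import pandas as pd

    rows = []
    for chrom in seg.layout.chrom_names:
        states = seg.states[chrom]
        length = seg.layout.length_of(chrom)
        change = np.flatnonzero(np.diff(states)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [states.size]))
        for s, e in zip(starts, ends):
            rows.append(
                {"chrom": chrom, "start": s * seg.layout.bin_size,
                 "end": min(e * seg.layout.bin_size, length), "name": f"E{states[s]}"}
            )
    return IntervalSet(pd.DataFrame(rows))
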
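"""Genomewide score tracks: expert tracks, ChromScore, quantile normalization.

Each expert is applied at every 25-bp interval of the genome, predicting the
activating probability at the interval's center nucleotide (the 13th base).
ChromScore is the per-bin mean over expert tracks. For analyses that compare
score distributions directly across experts, tracks are quantile-normalized
onto a common reference distribution: expert scores at a random genomic
sample are sorted, the per-rank median across experts defines the reference,
and each expert's scores are mapped through 1000 rank-quantile bins onto it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .experts import ExpertEnsemble, predict_expert
from .features import CellInputs, FeatureTransform, assemble_features
from .genome_io import GenomeLayout, IntervalSet

DEFAULT_N_QUANTILE_BINS = 1000
# production-scale sampling uses 10,000,000 (normalization reference) and
# 500,000 (pairwise correlations) positions; these defaults are scaled to
# the mini-genome fixtures
DEFAULT_NORMALIZATION_SAMPLE = 100_000
DEFAULT_CORRELATION_SAMPLE = 50_000

CENTER_OFFSET = 12  # 13th nucleotide of a 25-bp bin, 0-based


class TrackError(ValueError):
    pass


@dataclass
class ScoreTrack:
    """Per-cell-type score per 25-bp bin, one vector per chromosome."""

    cell_type: str
    source: str
    layout: GenomeLayout
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, arr in self.data.items():
            expected = self.layout.n_bins(chrom)
            if arr.size != expected:
                raise TrackError(
                    f"{chrom}: {arr.size} bins, layout expects {expected}"
                )

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.data[c] for c in self.layout.chrom_names])

    def bin_values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Score of the bin containing each base position."""
        bins = np.asarray(positions, dtype=np.int64) // self.layout.bin_size
        return self.data[chrom][bins]


def bin_centers(layout: GenomeLayout, chrom: str) -> np.ndarray:
    """Reference nucleotide of each bin: bin start + 12, clamped to the chromosome."""
    starts = np.arange(layout.n_bins(chrom), dtype=np.int64) * layout.bin_size
    return np.minimum(starts + CENTER_OFFSET, layout.length_of(chrom) - 1)


def score_genome(
    ens: ExpertEnsemble,
    cell: CellInputs,
    transform: FeatureTransform,
    layout: GenomeLayout | None = None,
) -> ScoreTrack:
    """Apply one expert at every 25-bp interval of the genome."""
    layout = layout or cell.layout
    missing = [m for m in transform.mark_names if m not in cell.signals]
    if missing:
        raise TrackError(f"cell {cell.cell_type} lacks signal for mark(s): {missing}")
    data = {}
    for chrom in layout.chrom_names:
        refs = bin_centers(layout, chrom)
        X = assemble_features([chrom] * refs.size, refs, cell, transform)
        data[chrom] = predict_expert(ens, X)
    return ScoreTrack(cell.cell_type, ens.name, layout, data)


def chromscore(expert_tracks: list[ScoreTrack], source: str = "ChromScore") -> ScoreTrack:
    """Per-bin mean of expert tracks."""
    if not expert_tracks:
        raise TrackError("need at least one expert track")
    first = expert_tracks[0]
    for t in expert_tracks[1:]:
        if t.layout.chrom_names != first.layout.chrom_names or t.layout.chrom_lengths != first.layout.chrom_lengths:
            raise TrackError("expert tracks have mismatched layouts")
    data = {
        chrom: np.mean([t.data[chrom] for t in expert_tracks], axis=0)
        for chrom in first.layout.chrom_names
    }
    return ScoreTrack(first.cell_type, source, first.layout, data)


def sample_genome_positions(
    layout: GenomeLayout,
    n: int,
    blacklist: IntervalSet | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random base positions, rejecting excluded regions.

    Returns (chrom indices, positions).
    """
    masks = None
    if blacklist is not None and len(blacklist):
        masks = {c: blacklist.coverage_mask(c, layout.length_of(c)) for c in layout.chrom_names}
        if all(m.all() for m in masks.values()):
            raise TrackError("excluded regions cover the whole genome")
    lengths = np.array(layout.chrom_lengths, dtype=np.int64)
    cum = np.concatenate(([0], np.cumsum(lengths)))
    chosen_c, chosen_p = [], []
    got = 0
    while got < n:
        draw = rng.integers(0, cum[-1], size=max(1024, 2 * (n - got)))
        ci = np.searchsorted(cum, draw, side="right") - 1
        pos = draw - cum[ci]
        if masks is not None:
            ok = np.array(
                [not masks[layout.chrom_names[c]][p] for c, p in zip(ci, pos)], dtype=bool
            )
            ci, pos = ci[ok], pos[ok]
        take = min(n - got, ci.size)
        chosen_c.append(ci[:take])
        chosen_p.append(pos[:take])
        got += take
    return np.concatenate(chosen_c), np.concatenate(chosen_p)


@dataclass
class QuantileMap:
    """Per-expert monotone mapping from score rank-quantiles to reference values."""

    n_bins: int
    sorted_samples: dict[str, np.ndarray]  # expert -> sorted sampled scores
    bin_values: dict[str, np.ndarray]      # expert -> (n_bins,) normalized value

    def normalize_values(self, expert: str, values: np.ndarray) -> np.ndarray:
        if expert not in self.sorted_samples:
            raise TrackError(f"expert {expert!r} not in quantile map")
        s = self.sorted_samples[expert]
        n = s.size
        # rank of each value in the sampled distribution; tied scores share
        # the same rank and hence the same (lower) quantile bin
        rank = np.clip(np.searchsorted(s, values, side="right") - 1, 0, n - 1)
        frac = rank / max(n - 1, 1)
        bins = np.minimum((frac * self.n_bins).astype(np.int64), self.n_bins - 1)
        return self.bin_values[expert][bins]


def build_quantile_map(
    expert_tracks: dict[str, ScoreTrack],
    blacklist: IntervalSet | None = None,
    n_sample: int = DEFAULT_NORMALIZATION_SAMPLE,
    n_bins: int = DEFAULT_N_QUANTILE_BINS,
    seed: int = 0,
) -> QuantileMap:
    """Fit the quantile-normalization map on a random genomic sample.

    All experts are evaluated at the same sampled positions; the reference
    distribution is the per-rank median across experts of the sorted scores.
    """
    if n_sample < n_bins:
        raise TrackError("sample size must be at least the number of quantile bins")
    names = sorted(expert_tracks)
    layout = expert_tracks[names[0]].layout
    rng = np.random.default_rng(seed)
    ci, pos = sample_genome_positions(layout, n_sample, blacklist, rng)
    sorted_samples = {}
    for name in names:
        track = expert_tracks[name]
        vals = np.empty(n_sample)
        for c in np.unique(ci):
            idx = ci == c
            vals[idx] = track.bin_values_at(layout.chrom_names[c], pos[idx])
        sorted_samples[name] = np.sort(vals)
    reference = np.median(np.stack([sorted_samples[n_] for n_ in names]), axis=0)
    # per-bin normalized value: mean reference value over the ranks in the bin
    edges = (np.arange(n_bins + 1) / n_bins * (n_sample - 1)).astype(np.int64)
    edges[-1] = n_sample - 1
    bin_values = {}
    for name in names:
        vals = np.empty(n_bins)
        for b in range(n_bins):
            lo, hi = edges[b], max(edges[b + 1], edges[b] + 1)
            vals[b] = reference[lo:hi].mean()
        bin_values[name] = np.maximum.accumulate(vals)  # enforce monotonicity
    return QuantileMap(n_bins, sorted_samples, bin_values)


def normalize_scores(qmap: QuantileMap, track: ScoreTrack) -> ScoreTrack:
    """Map one expert's track through its fitted quantile mapping."""
    data = {
        chrom: qmap.normalize_values(track.source, arr) for chrom, arr in track.data.items()
    }
    return ScoreTrack(track.cell_type, f"{track.source}-normalized", track.layout, data)


def normalized_chromscore(
    qmap: QuantileMap, expert_tracks: dict[str, ScoreTrack]
) -> ScoreTrack:
    """Mean of quantile-normalized expert tracks."""
    normalized = [normalize_scores(qmap, t) for t in expert_tracks.values()]
    return chromscore(normalized, source="ChromScore-normalized")


def pairwise_track_correlation(
    tracks: dict[str, ScoreTrack],
    blacklist: IntervalSet | None = None,
    n_sample: int = DEFAULT_CORRELATION_SAMPLE,
    seed: int = 0,
) -> tuple[list[str], np.ndarray]:
    """Pearson correlation matrix between tracks at randomly sampled positions.

    Zero-variance tracks yield NaN rows/columns (correlation undefined).
    """
    names = sorted(tracks)
    if len(names) < 2:
        raise TrackError("need at least two tracks")
    layout = tracks[names[0]].layout
    rng = np.random.default_rng(seed)
    ci, pos = sample_genome_positions(layout, n_sample, blacklist, rng)
    M = np.empty((len(names), n_sample))
    for i, name in enumerate(names):
        for c in np.unique(ci):
            idx = ci == c
            M[i, idx] = tracks[name].bin_values_at(layout.chrom_names[c], pos[idx])
    sds = M.std(axis=1)
    degenerate = sds <= 1e-12 * np.maximum(1.0, np.abs(M).max(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(M)
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    np.fill_diagonal(corr, np.where(degenerate, np.nan, 1.0))
    return names, corr


def write_score_bedgraph(track: ScoreTrack, path, decimals: int = 6) -> None:
    """Emit a score track as 25-bp-resolution bedGraph."""
    layout = track.layout
    with open(path, "w") as fh:
        for chrom in layout.chrom_names:
            arr = track.data[chrom]
            length = layout.length_of(chrom)
            for b, v in enumerate(arr):
                s = b * layout.bin_size
                e = min(s + layout.bin_size, length)
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.{decimals}f}\n")
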
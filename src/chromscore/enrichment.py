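"""Overlap fold enrichments of segmentations and score tracks.

Fold enrichment of an annotation in a state is the annotation's frequency
within the state divided by its genomewide frequency. Segmentation-level
enrichments are computed at 25-bp bin resolution (states are constant within
bins, so base-level and bin-level counting agree); peak-center enrichments
count single bases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import GenomeLayout, IntervalSet
from .scorehmm import Segmentation
from .tracks import ScoreTrack, sample_genome_positions


class EnrichmentError(ValueError):
    pass


def _state_base_counts(seg: Segmentation) -> np.ndarray:
    """Bases per state (1..K), from bin assignments truncated at chromosome ends."""
    counts = np.zeros(seg.K + 1, dtype=np.int64)
    for chrom in seg.layout.chrom_names:
        counts += np.bincount(seg.state_per_base(chrom), minlength=seg.K + 1)
    return counts


def overlap_fold_enrichment(
    seg: Segmentation, anno: IntervalSet, layout: GenomeLayout | None = None
) -> pd.DataFrame:
    """Per-state fold enrichment of an annotation's base coverage.

    fold(state) = (annotated bases in state / state bases)
                / (annotated bases genomewide / genome bases).
    States with zero bases get NaN.
    """
    layout = layout or seg.layout
    genome = layout.genome_length
    state_bases = _state_base_counts(seg)
    anno_in_state = np.zeros(seg.K + 1, dtype=np.int64)
    anno_total = 0
    for chrom in layout.chrom_names:
        mask = anno.coverage_mask(chrom, layout.length_of(chrom))
        anno_total += int(mask.sum())
        spb = seg.state_per_base(chrom)
        anno_in_state += np.bincount(spb[mask], minlength=seg.K + 1)
    folds = np.full(seg.K, np.nan)
    background = anno_total / genome
    for k in range(1, seg.K + 1):
        if state_bases[k] > 0 and background > 0:
            folds[k - 1] = (anno_in_state[k] / state_bases[k]) / background
    return pd.DataFrame(
        {
            "state": [f"E{k}" for k in range(1, seg.K + 1)],
            "state_bases": state_bases[1:],
            "genome_pct": 100 * state_bases[1:] / genome,
            "anno_bases_in_state": anno_in_state[1:],
            "fold": folds,
        }
    )


def peak_centers(peaks: IntervalSet) -> pd.DataFrame:
    """Center base of each peak: start + floor(len/2)."""
    df = peaks.records
    return pd.DataFrame(
        {"chrom": df["chrom"], "pos": df["start"] + (df["end"] - df["start"]) // 2}
    )


def peak_center_enrichment(
    seg: Segmentation, peaks: IntervalSet, multicount: bool = True
) -> pd.DataFrame:
    """Per-state fold enrichment of peak-center bases.

    With ``multicount`` a base that is the center of several peaks counts
    once per peak; otherwise duplicate center bases count once.
    """
    if len(peaks) == 0:
        raise EnrichmentError("no peaks provided")
    centers = peak_centers(peaks)
    if not multicount:
        centers = centers.drop_duplicates()
    genome = seg.layout.genome_length
    state_bases = _state_base_counts(seg)
    counts = np.zeros(seg.K + 1, dtype=np.int64)
    for chrom, grp in centers.groupby("chrom", sort=False):
        spb = seg.state_per_base(chrom)
        counts += np.bincount(spb[grp["pos"].to_numpy()], minlength=seg.K + 1)
    total = counts.sum()
    folds = np.full(seg.K, np.nan)
    for k in range(1, seg.K + 1):
        if state_bases[k] > 0 and total > 0:
            folds[k - 1] = (counts[k] / total) / (state_bases[k] / genome)
    return pd.DataFrame(
        {
            "state": [f"E{k}" for k in range(1, seg.K + 1)],
            "state_bases": state_bases[1:],
            "genome_pct": 100 * state_bases[1:] / genome,
            "centers": counts[1:],
            "fold": folds,
        }
    )


def cumulative_enrichment_curve(enrich: pd.DataFrame) -> pd.DataFrame:
    """Cumulative fold-enrichment curve over states sorted by descending fold.

    Each state contributes genome% x fold = the percentage of peak centers it
    contains; cumulative sums of that, divided by cumulative genome %, give
    the cumulative fold. The curve is non-increasing and ends at fold 1.
    """
    df = enrich.dropna(subset=["fold"]).sort_values("fold", ascending=False).reset_index(drop=True)
    genome_pct = df["genome_pct"].to_numpy()
    contained_pct = genome_pct * df["fold"].to_numpy()  # % of peak centers in state
    cum_genome = np.cumsum(genome_pct)
    cum_fold = np.cumsum(contained_pct) / cum_genome
    return pd.DataFrame(
        {"state": df["state"], "cum_genome_pct": cum_genome, "cum_fold": cum_fold}
    )


def positional_enrichment(
    seg: Segmentation,
    anchors: IntervalSet,
    half_window: int = 12_000,
    step: int = 200,
) -> pd.DataFrame:
    """Per-state fold enrichment at signed offsets around stranded anchors.

    Offsets for negative-strand anchors are mirrored (offset +x reads the
    base at anchor-x). Windows running off a chromosome are truncated. fold =
    observed state frequency at the offset / genomewide state frequency.
    """
    df = anchors.records
    if df["strand"].isna().any() or (~df["strand"].isin(["+", "-"])).any():
        raise EnrichmentError("anchors must carry +/- strands")
    offsets = np.arange(-half_window, half_window + 1, step)
    counts = np.zeros((offsets.size, seg.K + 1), dtype=np.int64)
    for row in df.itertuples(index=False):
        spb = seg.state_per_base(row.chrom)
        anchor = row.start
        pos = anchor + offsets if row.strand == "+" else anchor - offsets
        ok = (pos >= 0) & (pos < spb.size)
        counts[np.arange(offsets.size)[ok], spb[pos[ok]]] += 1
    state_bases = _state_base_counts(seg)
    genome = seg.layout.genome_length
    rows = []
    for oi, off in enumerate(offsets):
        total = counts[oi].sum()
        for k in range(1, seg.K + 1):
            bg = state_bases[k] / genome
            fold = (counts[oi, k] / total) / bg if total > 0 and bg > 0 else np.nan
            rows.append({"offset": int(off), "state": f"E{k}", "fold": fold})
    return pd.DataFrame(rows)


def quantile_fold_enrichment(
    track: ScoreTrack,
    element_sets: dict[str, IntervalSet],
    n_quantiles: int = 200,
    n_sample: int = 50_000,
    blacklist: IntervalSet | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fold enrichment of element sets across score quantiles.

    Random genome positions are binned into score quantiles (tied scores
    share the lower quantile); fold(q, set) = membership frequency in the
    quantile / membership frequency in the whole sample.
    """
    if n_sample < n_quantiles:
        raise EnrichmentError("sample size must be at least the number of quantiles")
    layout = track.layout
    rng = np.random.default_rng(seed)
    ci, pos = sample_genome_positions(layout, n_sample, blacklist, rng)
    scores = np.empty(n_sample)
    members = {name: np.zeros(n_sample, dtype=bool) for name in element_sets}
    for c in np.unique(ci):
        chrom = layout.chrom_names[c]
        idx = ci == c
        scores[idx] = track.bin_values_at(chrom, pos[idx])
        for name, ivs in element_sets.items():
            mask = ivs.coverage_mask(chrom, layout.length_of(chrom))
            members[name][idx] = mask[pos[idx]]
    # quantile of each sample: rank among sampled scores, ties -> lower quantile
    order = np.argsort(scores, kind="stable")
    ranks = np.empty(n_sample, dtype=np.int64)
    ranks[order] = np.arange(n_sample)
    # tied values share the rank of their first occurrence
    srt = scores[order]
    first_of_value = np.searchsorted(srt, scores, side="left")
    quant = np.minimum(
        (first_of_value / max(n_sample - 1, 1) * n_quantiles).astype(np.int64),
        n_quantiles - 1,
    )
    rows = []
    for name in element_sets:
        m = members[name]
        overall = m.mean()
        if overall == 0:
            import warnings

            warnings.warn(f"element set {name!r} never sampled; folds are 0", stacklevel=2)
        for q in range(n_quantiles):
            in_q = quant == q
            n_q = int(in_q.sum())
            if n_q == 0:
                fold = np.nan
            elif overall == 0:
                fold = 0.0
            else:
                fold = (m[in_q].mean()) / overall
            rows.append({"set": name, "quantile": q, "n": n_q, "fold": fold})
    return pd.DataFrame(rows)
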
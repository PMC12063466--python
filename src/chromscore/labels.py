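"""Activating/neutral label extraction for functional characterization data.

Each public function implements one dataset family's labeling scheme and
emits records in a harmonized form: a genomic reference nucleotide (the base
taken to represent the tested region's regulatory activity), a binary label
(``activating`` / ``neutral``) and the raw readout value. Regions showing
evidence of repression are excluded rather than labeled, so experts are
trained on a strictly two-class problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import GenomeLayout, IntervalSet

ACTIVATING = "activating"
NEUTRAL = "neutral"

MAIN_CHROMS = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX",)

RECORD_COLUMNS = ["chrom", "ref_pos", "label", "raw_value"]


@dataclass
class FunctionalDataset:
    """Harmonized labeled loci from one functional characterization dataset."""

    name: str
    cell_type: str
    assay_class: str  # plasmid_mpra | plasmid_starr | crispr
    records: pd.DataFrame  # chrom, ref_pos, label, raw_value

    def __post_init__(self) -> None:
        df = self.records.reset_index(drop=True)
        missing = set(RECORD_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"dataset records missing columns {sorted(missing)}")
        bad = set(df["label"]) - {ACTIVATING, NEUTRAL}
        if bad:
            raise ValueError(f"non-binary labels present: {sorted(bad)}")
        self.records = df[RECORD_COLUMNS + [c for c in df.columns if c not in RECORD_COLUMNS]]

    @property
    def n_activating(self) -> int:
        return int((self.records["label"] == ACTIVATING).sum())

    @property
    def n_neutral(self) -> int:
        return int((self.records["label"] == NEUTRAL).sum())

    def y(self) -> np.ndarray:
        return (self.records["label"] == ACTIVATING).to_numpy()

    def loci(self) -> list[tuple[str, int]]:
        return list(zip(self.records["chrom"], self.records["ref_pos"].astype(int)))


def filter_main_chromosomes(records: pd.DataFrame, allowed=MAIN_CHROMS) -> pd.DataFrame:
    """Keep loci on the autosomes and chrX only."""
    return records[records["chrom"].isin(allowed)].reset_index(drop=True)


def region_midpoint(start: int, end: int) -> int:
    """Deterministic midpoint convention: start + floor(len/2)."""
    return int(start) + (int(end) - int(start)) // 2


def label_sharpr(
    region_scores: pd.DataFrame,
    act_thresh: float = 1.0,
    rep_thresh: float = -1.0,
    interval_size: int = 5,
) -> pd.DataFrame:
    """Label densely tiled regions from per-5-bp regulatory activity scores.

    For each region, S_absmax is the score at the position of maximum
    absolute value (kept signed). Regions with S_absmax above ``act_thresh``
    are activating, those below ``rep_thresh`` are dropped as likely
    repressive, the rest are neutral. The reference nucleotide is the center
    base of the winning 5-bp interval.

    ``region_scores`` columns: region, chrom, region_start, interval_index, score.
    """
    if len(region_scores) == 0:
        raise ValueError("tiled region table has no scores")
    rows = []
    for region, grp in region_scores.groupby("region", sort=False):
        scores = grp.sort_values("interval_index")["score"].to_numpy()
        if scores.size == 0:
            raise ValueError(f"region {region!r} has no scores")
        k = int(np.argmax(np.abs(scores)))
        s_absmax = float(scores[k])
        if s_absmax < rep_thresh:
            continue  # likely repressive; excluded from training
        label = ACTIVATING if s_absmax > act_thresh else NEUTRAL
        start = int(grp["region_start"].iloc[0])
        ref = start + k * interval_size + interval_size // 2
        rows.append(
            {"chrom": grp["chrom"].iloc[0], "ref_pos": ref, "label": label,
             "raw_value": s_absmax, "region": region}
        )
    return pd.DataFrame(rows, columns=["chrom", "ref_pos", "label", "raw_value", "region"])


def label_pvalue(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Label reporter constructs by their activity p-value (activating iff p < alpha).

    The reference nucleotide is the construct center (the designed motif center).
    ``records`` columns: construct, chrom, start, end, p.
    """
    p = records["p"].to_numpy(dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = pd.DataFrame(
        {
            "chrom": records["chrom"],
            "ref_pos": [region_midpoint(s, e) for s, e in zip(records["start"], records["end"])],
            "label": np.where(p < alpha, ACTIVATING, NEUTRAL),
            "raw_value": p,
        }
    )
    return out.reset_index(drop=True)


def label_top_fraction_peaks(peaks: pd.DataFrame, frac: float = 0.10) -> pd.DataFrame:
    """Activating labels for the top fraction of peaks by fold-change score.

    The top floor(frac*N) peaks are labeled; ties at the cutoff score are all
    included, so the count can slightly exceed floor(frac*N). The reference
    nucleotide is the peak center.
    """
    if len(peaks) == 0:
        raise ValueError("no peaks provided")
    scores = peaks["fold_change"].to_numpy(dtype=float)
    n_top = int(np.floor(frac * len(peaks)))
    if n_top == 0:
        chosen = np.zeros(len(peaks), dtype=bool)
    else:
        cutoff = np.sort(scores)[::-1][n_top - 1]
        chosen = scores >= cutoff
    sel = peaks[chosen]
    return pd.DataFrame(
        {
            "chrom": sel["chrom"],
            "ref_pos": [region_midpoint(s, e) for s, e in zip(sel["start"], sel["end"])],
            "label": ACTIVATING,
            "raw_value": sel["fold_change"].to_numpy(dtype=float),
        }
    ).reset_index(drop=True)


def sample_neutral_background(
    layout: GenomeLayout,
    blacklist: IntervalSet,
    n_activating: int,
    ratio: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample ratio*n_activating neutral bases uniformly, avoiding excluded regions."""
    n_needed = ratio * n_activating
    masks = {c: blacklist.coverage_mask(c, layout.length_of(c)) for c in layout.chrom_names}
    if all(m.all() for m in masks.values()):
        raise ValueError("excluded regions cover the entire genome")
    lengths = np.array([layout.length_of(c) for c in layout.chrom_names], dtype=np.int64)
    cum = np.concatenate(([0], np.cumsum(lengths)))
    rng = np.random.default_rng(seed)
    chroms: list[str] = []
    positions: list[int] = []
    while len(positions) < n_needed:
        draw = rng.integers(0, cum[-1], size=max(64, 2 * (n_needed - len(positions))))
        ci = np.searchsorted(cum, draw, side="right") - 1
        pos = draw - cum[ci]
        for c, p in zip(ci, pos):
            if len(positions) >= n_needed:
                break
            chrom = layout.chrom_names[c]
            if masks[chrom][p]:
                continue
            chroms.append(chrom)
            positions.append(int(p))
    return pd.DataFrame(
        {"chrom": chroms, "ref_pos": positions, "label": NEUTRAL, "raw_value": np.nan}
    )


def label_hidra(
    drivers: pd.DataFrame,
    layout: GenomeLayout,
    ratio: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Label episomal driver elements by RNA/DNA ratio (activating iff ratio > 1).

    Neutral loci are sampled from tiled-but-not-active regions at the given
    ratio per activating element.

    ``drivers`` columns: element, chrom, start, end, rna_dna_ratio,
    tile_start, tile_end.
    """
    ratios = drivers["rna_dna_ratio"].to_numpy(dtype=float)
    if (ratios <= 0).any():
        raise ValueError("RNA/DNA ratios must be positive")
    active = ratios > 1.0
    act_rows = pd.DataFrame(
        {
            "chrom": drivers["chrom"][active],
            "ref_pos": [region_midpoint(s, e)
                        for s, e in zip(drivers["start"][active], drivers["end"][active])],
            "label": ACTIVATING,
            "raw_value": ratios[active],
        }
    ).reset_index(drop=True)

    # neutral universe: tiled regions minus active driver footprints
    universe: list[tuple[str, int, int]] = []
    act_iv = [
        (c, int(s), int(e))
        for c, s, e in zip(drivers["chrom"][active], drivers["start"][active], drivers["end"][active])
    ]
    for row in drivers.itertuples(index=False):
        segs = [(row.chrom, int(row.tile_start), int(row.tile_end))]
        for c, s, e in act_iv:
            segs = _subtract(segs, c, s, e)
        universe.extend(segs)
    total = sum(e - s for _, s, e in universe)
    if total == 0:
        raise ValueError("tiled-minus-active universe is empty")
    rng = np.random.default_rng(seed)
    n_needed = ratio * len(act_rows)
    cum = np.concatenate(([0], np.cumsum([e - s for _, s, e in universe])))
    draw = rng.integers(0, total, size=n_needed)
    si = np.searchsorted(cum, draw, side="right") - 1
    neut_rows = pd.DataFrame(
        {
            "chrom": [universe[i][0] for i in si],
            "ref_pos": [int(universe[i][1] + d - cum[i]) for i, d in zip(si, draw)],
            "label": NEUTRAL,
            "raw_value": np.nan,
        }
    )
    return pd.concat([act_rows, neut_rows], ignore_index=True)


def _subtract(segs, chrom, s, e):
    out = []
    for c, a, b in segs:
        if c != chrom or e <= a or s >= b:
            out.append((c, a, b))
            continue
        if a < s:
            out.append((c, a, s))
        if e < b:
            out.append((c, e, b))
    return out


def label_crispri(records: pd.DataFrame, scheme: str, alpha: float = 0.05) -> pd.DataFrame:
    """Label CRISPRi-perturbed elements from per-element-gene regression rows.

    ``gasperini`` scheme: keep rows with negative beta that are not flagged as
    outliers; a target is activating if any of its measured genes has adjusted
    p below alpha. ``fulco`` scheme: drop element-gene pairs that are
    underpowered (power < 0.8) or show a positive expression change (suggesting
    repression); an element is activating if it appears in at least one
    significant pair. The reference nucleotide is the element midpoint.
    """
    if scheme == "gasperini":
        required = {"target", "chrom", "start", "end", "beta", "p_adj", "outlier_gene"}
    elif scheme == "fulco":
        required = {"target", "chrom", "start", "end", "power", "fraction_change", "p_adj"}
    else:
        raise ValueError(f"unknown CRISPRi scheme {scheme!r}")
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns for scheme {scheme!r}: {sorted(missing)}")

    if scheme == "gasperini":
        kept = records[(records["beta"] < 0) & (~records["outlier_gene"].astype(bool))]
    else:
        kept = records[(records["power"] >= 0.8) & (records["fraction_change"] < 0)]

    rows = []
    for target, grp in records.groupby("target", sort=False):
        kgrp = kept[kept["target"] == target]
        sig = bool((kgrp["p_adj"] < alpha).any()) if len(kgrp) else False
        if scheme == "fulco" and len(kgrp) == 0 and len(grp) > 0:
            # element entirely filtered out of testable pairs: still a tested
            # element with no evidence of activation
            sig = False
        first = grp.iloc[0]
        rows.append(
            {"chrom": first["chrom"],
             "ref_pos": region_midpoint(first["start"], first["end"]),
             "label": ACTIVATING if sig else NEUTRAL,
             "raw_value": float(kgrp["p_adj"].min()) if len(kgrp) else np.nan}
        )
    return pd.DataFrame(rows, columns=["chrom", "ref_pos", "label", "raw_value"])


def build_dataset(
    name: str,
    cell_type: str,
    assay_class: str,
    activating_records: pd.DataFrame,
    layout: GenomeLayout | None = None,
    blacklist: IntervalSet | None = None,
    neutral_ratio: int | None = None,
    seed: int = 0,
) -> FunctionalDataset:
    """Assemble a FunctionalDataset, optionally adding sampled neutral background."""
    parts = [activating_records]
    if neutral_ratio is not None:
        n_act = int((activating_records["label"] == ACTIVATING).sum())
        parts.append(
            sample_neutral_background(layout, blacklist, n_act, ratio=neutral_ratio, seed=seed)
        )
    records = pd.concat(parts, ignore_index=True)
    records = filter_main_chromosomes(records, allowed=tuple(layout.chrom_names) if layout else MAIN_CHROMS)
    if layout is not None:
        lengths = layout.lengths
        for chrom, pos in zip(records["chrom"], records["ref_pos"]):
            if not 0 <= pos < lengths[chrom]:
                raise ValueError(f"reference nucleotide {chrom}:{pos} outside the genome")
    return FunctionalDataset(name, cell_type, assay_class, records)
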
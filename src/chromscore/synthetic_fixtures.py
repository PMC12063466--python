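"""Synthetic mini-genome fixtures with planted regulatory elements.

The generator emulates the inputs the pipeline consumes in production —
per-cell-type chromatin-mark signal tracks, narrow peak calls, a 25-state
chromatin-state annotation, an excluded-regions list, and functional
characterization readouts (tiling MPRA scores, construct p-values, episomal
reporter peaks, RNA/DNA ratios, CRISPRi regression tables) — on a genome
small enough that every downstream stage runs in seconds.

Planted truth: each cell type carries a set of active elements with an
activity level in [0,1]. Activating marks (accessibility, acetylation,
H3K4 methylation, H2A.Z) are elevated in a smooth ~2-kb bump around active
elements; repressive marks (H3K27me3, H3K9me3) are elevated on a disjoint
planted set. Assay readouts are noisy monotone functions of activity, shaped
like the scheme they imitate. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GenomeLayout, IntervalSet, SignalTrack

MARKS = (
    "DNase",
    "H2A.Z",
    "H3K27ac",
    "H3K27me3",
    "H3K36me3",
    "H3K4me1",
    "H3K4me2",
    "H3K4me3",
    "H3K79me2",
    "H3K9ac",
    "H3K9me3",
    "H4K20me1",
)

# relative amplitude of the planted bump per mark
ACTIVATING_WEIGHTS = {
    "DNase": 1.0,
    "H3K27ac": 1.0,
    "H3K9ac": 0.8,
    "H3K4me1": 0.8,
    "H3K4me2": 0.7,
    "H3K4me3": 0.5,
    "H2A.Z": 0.6,
}
REPRESSIVE_WEIGHTS = {"H3K27me3": 1.0, "H3K9me3": 0.8}
TRANSCRIPTION_WEIGHTS = {"H3K36me3": 0.6, "H3K79me2": 0.5, "H4K20me1": 0.4}

N_STATES = 25
STATE_QUIESCENT = 25
STATE_TSS = 1
STATE_ENH_STRONG = 13
STATE_ENH_WEAK = 14
STATE_REPRESSED = 24

ASSAY_SCHEMES = ("sharpr", "pvalue", "starr_peaks", "hidra", "crispri")


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for the synthetic mini-genome."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 500_000
    n_cell_types: int = 3
    n_elements: int = 40       # active elements per cell type
    n_repressive: int = 15     # repressively marked elements per cell type
    n_genes: int = 10          # planted genes per chromosome
    effect: float = 3.0        # bump amplitude at activity 1, signal units
    noise_sd: float = 0.25     # signal noise SD (per 25-bp block)
    baseline: float = 0.10     # background signal level
    bump_sd: float = 300.0     # spatial spread of the planted bump, bases
    bin_size: int = 25
    schemes: tuple[str, ...] = ASSAY_SCHEMES

    def __post_init__(self) -> None:
        for name, val in (
            ("n_chroms", self.n_chroms),
            ("chrom_length", self.chrom_length),
            ("n_cell_types", self.n_cell_types),
            ("n_elements", self.n_elements),
        ):
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.schemes) - set(ASSAY_SCHEMES)
        if unknown:
            raise ValueError(f"unknown assay schemes: {sorted(unknown)}")

    @property
    def layout(self) -> GenomeLayout:
        names = tuple(f"chr{i + 1}" for i in range(self.n_chroms))
        return GenomeLayout(names, (self.chrom_length,) * self.n_chroms, self.bin_size)

    @property
    def cell_types(self) -> tuple[str, ...]:
        return tuple(f"CT{i + 1}" for i in range(self.n_cell_types))


@dataclass
class PlantedTruth:
    """Ground truth for one synthetic cell type."""

    cell_type: str
    elements: IntervalSet           # active elements; score = activity in [0,1]
    repressive: IntervalSet         # repressively marked elements
    genes: pd.DataFrame             # chrom, tss, strand, rpkm
    activity: np.ndarray            # per-element activity, aligned with elements
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def element_centers(self) -> pd.DataFrame:
        df = self.elements.records
        return pd.DataFrame(
            {
                "chrom": df["chrom"],
                "center": df["start"] + (df["end"] - df["start"]) // 2,
                "activity": df["score"],
            }
        )


@dataclass
class CellFixture:
    """All per-cell-type inputs the pipeline needs."""

    cell_type: str
    truth: PlantedTruth
    signals: dict[str, SignalTrack]
    peaks: dict[str, IntervalSet]
    states: IntervalSet


def _rng(cfg_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg_seed, spawn_key=tuple(key)))


def _place_elements(cfg: FixtureConfig, rng: np.random.Generator):
    """Pick disjoint element centers on a 5-kb grid, away from chromosome ends."""
    spacing = 5_000
    margin = 2_500
    per_chrom_slots = (cfg.chrom_length - 2 * margin) // spacing
    total_slots = per_chrom_slots * cfg.n_chroms
    need = cfg.n_elements + cfg.n_repressive
    if need > total_slots:
        raise ValueError(
            f"cannot place {need} elements in {total_slots} available 5-kb slots"
        )
    slots = rng.choice(total_slots, size=need, replace=False)
    chroms = slots // per_chrom_slots
    centers = margin + (slots % per_chrom_slots) * spacing + spacing // 2
    return chroms[: cfg.n_elements], centers[: cfg.n_elements], chroms[cfg.n_elements:], centers[cfg.n_elements:]


def _bump(length: int, center: int, amplitude: float, sd: float) -> tuple[slice, np.ndarray]:
    half = int(4 * sd)
    lo, hi = max(0, center - half), min(length, center + half)
    x = np.arange(lo, hi)
    return slice(lo, hi), amplitude * np.exp(-0.5 * ((x - center) / sd) ** 2)


def simulate_cell_signals(cfg: FixtureConfig, cell_index: int = 0) -> tuple[
    GenomeLayout, PlantedTruth, dict[str, SignalTrack], dict[str, IntervalSet], IntervalSet
]:
    """Simulate one cell type's signal tracks, peaks and state annotation.

    Returns (layout, truth, per-mark signal, per-mark peaks, 25-state annotation).
    """
    layout = cfg.layout
    cell = cfg.cell_types[cell_index]
    rng = _rng(cfg.seed, cell_index)

    act_chroms, act_centers, rep_chroms, rep_centers = _place_elements(cfg, rng)
    activity = rng.uniform(0.2, 1.0, size=cfg.n_elements)

    half_el = 150
    elements = IntervalSet.from_arrays(
        [layout.chrom_names[c] for c in act_chroms],
        act_centers - half_el,
        act_centers + half_el,
        names=[f"{cell}_el{i}" for i in range(cfg.n_elements)],
        scores=activity,
    )
    repressive = IntervalSet.from_arrays(
        [layout.chrom_names[c] for c in rep_chroms],
        rep_centers - half_el,
        rep_centers + half_el,
        names=[f"{cell}_rep{i}" for i in range(cfg.n_repressive)],
        scores=np.ones(cfg.n_repressive),
    )

    # planted genes: shared positions across cell types (seeded by genome only),
    # cell-specific expression driven by nearby element activity
    grng = _rng(cfg.seed, 10_000)
    gene_rows = []
    for ci, chrom in enumerate(layout.chrom_names):
        tss = np.sort(grng.integers(5_000, cfg.chrom_length - 5_000, size=cfg.n_genes))
        strands = grng.choice(["+", "-"], size=cfg.n_genes)
        for t, s in zip(tss, strands):
            gene_rows.append({"chrom": chrom, "tss": int(t), "strand": s})
    genes = pd.DataFrame(gene_rows)
    # expression: activity mass of planted active elements within 10 kb of the TSS
    expr = np.zeros(len(genes))
    el = elements.records
    for gi, row in genes.iterrows():
        near = el[(el["chrom"] == row["chrom"]) & ((el["start"] + half_el - row["tss"]).abs() < 10_000)]
        expr[gi] = near["score"].sum()
    genes["rpkm"] = np.maximum(0.0, 2.0 ** (3.0 * expr) - 1.0 + rng.normal(0, 0.1, len(genes)))

    truth = PlantedTruth(cell, elements, repressive, genes, activity, dict(layout.lengths))

    # signal: per-25-bp-block noise around a baseline, plus planted bumps
    n_bins = layout.n_bins(layout.chrom_names[0])
    signals: dict[str, SignalTrack] = {}
    for mi, mark in enumerate(MARKS):
        data = {}
        for ci, chrom in enumerate(layout.chrom_names):
            mrng = _rng(cfg.seed, cell_index, mi, ci)
            block_noise = mrng.normal(0.0, cfg.noise_sd, size=n_bins)
            arr = np.maximum(
                0.0, cfg.baseline + np.repeat(block_noise, cfg.bin_size)[: cfg.chrom_length]
            )
            if mark in ACTIVATING_WEIGHTS:
                w = ACTIVATING_WEIGHTS[mark]
                for c, cen, a in zip(act_chroms, act_centers, activity):
                    if layout.chrom_names[c] == chrom:
                        sl, bump = _bump(cfg.chrom_length, cen, cfg.effect * w * a, cfg.bump_sd)
                        arr[sl] += bump
            if mark in REPRESSIVE_WEIGHTS:
                w = REPRESSIVE_WEIGHTS[mark]
                for c, cen in zip(rep_chroms, rep_centers):
                    if layout.chrom_names[c] == chrom:
                        sl, bump = _bump(cfg.chrom_length, cen, cfg.effect * w, cfg.bump_sd)
                        arr[sl] += bump
            if mark in TRANSCRIPTION_WEIGHTS:
                w = TRANSCRIPTION_WEIGHTS[mark]
                gsub = genes[genes["chrom"] == chrom]
                for _, g in gsub.iterrows():
                    lvl = np.log2(g["rpkm"] + 1)
                    if lvl <= 0:
                        continue
                    body = slice(g["tss"], min(cfg.chrom_length, g["tss"] + 5_000))
                    if g["strand"] == "-":
                        body = slice(max(0, g["tss"] - 5_000), g["tss"])
                    arr[body] += 0.3 * w * lvl
            data[chrom] = arr
        signals[mark] = SignalTrack(data)

    peaks = {mark: _call_peaks(signals[mark], layout, cfg) for mark in MARKS}
    states = _annotate_states(cfg, layout, truth)
    return layout, truth, signals, peaks, states


def _call_peaks(track: SignalTrack, layout: GenomeLayout, cfg: FixtureConfig) -> IntervalSet:
    """Fixed-threshold peak calls on 25-bp-binned signal."""
    threshold = cfg.baseline + 0.25 * cfg.effect
    chroms, starts, ends = [], [], []
    for chrom in layout.chrom_names:
        binned = track.binned(chrom, cfg.bin_size)
        above = binned > threshold
        if not above.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            chroms.append(chrom)
            starts.append(int(s) * cfg.bin_size)
            ends.append(min(int(e) * cfg.bin_size, layout.length_of(chrom)))
    if not chroms:
        return IntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]))
    return IntervalSet.from_arrays(chroms, starts, ends)


def _annotate_states(cfg: FixtureConfig, layout: GenomeLayout, truth: PlantedTruth) -> IntervalSet:
    """25-label chromatin-state annotation consistent with planted truth."""
    chroms, starts, ends, names = [], [], [], []
    per_chrom = {c: np.full(layout.length_of(c), STATE_QUIESCENT, dtype=np.int8) for c in layout.chrom_names}
    for _, g in truth.genes.iterrows():
        arr = per_chrom[g["chrom"]]
        lo, hi = max(0, g["tss"] - 500), min(arr.size, g["tss"] + 500)
        arr[lo:hi] = STATE_TSS
    for row in truth.repressive.records.itertuples(index=False):
        arr = per_chrom[row.chrom]
        c = (row.start + row.end) // 2
        arr[max(0, c - 500): min(arr.size, c + 500)] = STATE_REPRESSED
    for row in truth.elements.records.itertuples(index=False):
        arr = per_chrom[row.chrom]
        c = (row.start + row.end) // 2
        state = STATE_ENH_STRONG if row.score > 0.5 else STATE_ENH_WEAK
        arr[max(0, c - 500): min(arr.size, c + 500)] = state
    for chrom, arr in per_chrom.items():
        change = np.flatnonzero(np.diff(arr)) + 1
        ss = np.concatenate(([0], change))
        ee = np.concatenate((change, [arr.size]))
        for s, e in zip(ss, ee):
            chroms.append(chrom)
            starts.append(int(s))
            ends.append(int(e))
            names.append(f"S{arr[s]}")
    return IntervalSet.from_arrays(chroms, starts, ends, names=names)


def make_blacklist(cfg: FixtureConfig) -> IntervalSet:
    """A small excluded-regions list: two 2-kb artifact-prone windows per chromosome."""
    rng = _rng(cfg.seed, 20_000)
    layout = cfg.layout
    chroms, starts = [], []
    for chrom in layout.chrom_names:
        for s in rng.integers(0, cfg.chrom_length - 2_000, size=2):
            chroms.append(chrom)
            starts.append(int(s))
    starts = np.array(starts)
    return IntervalSet.from_arrays(chroms, starts, starts + 2_000)


def simulate_cell(cfg: FixtureConfig, cell_index: int) -> CellFixture:
    layout, truth, signals, peaks, states = simulate_cell_signals(cfg, cell_index)
    return CellFixture(cfg.cell_types[cell_index], truth, signals, peaks, states)


def simulate_all_cells(cfg: FixtureConfig) -> list[CellFixture]:
    return [simulate_cell(cfg, i) for i in range(cfg.n_cell_types)]


# ---------------------------------------------------------------------------
# assay readout simulation


def simulate_assay_readouts(
    truth: PlantedTruth,
    scheme: str,
    seed: int,
    noise_sd: float = 0.25,
    layout: GenomeLayout | None = None,
) -> pd.DataFrame:
    """Emit a raw readout table shaped like the named assay scheme.

    Readouts are noisy monotone functions of planted element activity; each
    scheme also emits inactive/background records so downstream label
    extraction sees both classes.
    """
    if scheme not in ASSAY_SCHEMES:
        raise ValueError(f"unknown assay scheme {scheme!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(ASSAY_SCHEMES.index(scheme),)))
    if scheme == "sharpr":
        return _readout_sharpr(truth, rng, noise_sd)
    if scheme == "pvalue":
        return _readout_pvalue(truth, rng, noise_sd)
    if scheme == "starr_peaks":
        return _readout_starr_peaks(truth, rng, noise_sd)
    if scheme == "hidra":
        return _readout_hidra(truth, rng, noise_sd)
    if scheme == "crispri":
        return _readout_crispri(truth, rng, noise_sd)
    raise ValueError(f"unknown assay scheme {scheme!r}")


def _background_position(center: int, offset: int, limit: int, margin: int = 2_000) -> int:
    """Shift a background construct away from an element, staying inside the genome."""
    pos = center + offset
    if pos + margin > limit or pos - margin < 0:
        pos = center - offset
    return int(np.clip(pos, margin, limit - margin))


def _chrom_limit(truth: PlantedTruth, chrom: str) -> int:
    if truth.chrom_lengths:
        return truth.chrom_lengths[chrom]
    sub = truth.elements.records
    return int(sub[sub["chrom"] == chrom]["end"].max()) + 2_500


def _readout_sharpr(truth: PlantedTruth, rng, noise_sd) -> pd.DataFrame:
    """Tiling-MPRA-style per-5-bp regulatory activity scores per tiled region."""
    rows = []
    centers = truth.element_centers()
    n_int = 59  # 295-bp tiled region at 5-bp resolution
    for i, row in centers.iterrows():
        start = int(row["center"]) - (n_int * 5) // 2
        offs = (np.arange(n_int) - n_int // 2) * 5
        profile = 4.0 * row["activity"] * np.exp(-0.5 * (offs / 60.0) ** 2)
        scores = profile + rng.normal(0, noise_sd, n_int)
        for j, sc in enumerate(scores):
            rows.append(
                {"region": f"reg_act_{i}", "chrom": row["chrom"], "region_start": start,
                 "interval_index": j, "score": float(sc)}
            )
    # background tiled regions: pure noise
    for i in range(len(centers)):
        chrom = centers["chrom"].iloc[i]
        bg_center = _background_position(
            int(centers["center"].iloc[i]), 20_000, _chrom_limit(truth, chrom)
        )
        start = bg_center - (n_int * 5) // 2
        for j in range(n_int):
            rows.append(
                {"region": f"reg_bg_{i}", "chrom": chrom, "region_start": start,
                 "interval_index": j, "score": float(rng.normal(0, noise_sd))}
            )
    # repressively marked regions: negative tiling scores
    for i, row in enumerate(truth.repressive.records.itertuples(index=False)):
        start = (row.start + row.end) // 2 - (n_int * 5) // 2
        offs = (np.arange(n_int) - n_int // 2) * 5
        profile = -3.0 * np.exp(-0.5 * (offs / 60.0) ** 2)
        for j, sc in enumerate(profile + rng.normal(0, noise_sd, n_int)):
            rows.append(
                {"region": f"reg_rep_{i}", "chrom": row.chrom, "region_start": int(start),
                 "interval_index": j, "score": float(sc)}
            )
    return pd.DataFrame(rows)


def _readout_pvalue(truth: PlantedTruth, rng, noise_sd) -> pd.DataFrame:
    """Per-construct activity p-values against scrambled controls."""
    centers = truth.element_centers()
    rows = []
    for i, row in centers.iterrows():
        z = 4.0 * row["activity"] + rng.normal(0, 2.0 * noise_sd)
        rows.append(
            {"construct": f"con_act_{i}", "chrom": row["chrom"],
             "start": int(row["center"]) - 72, "end": int(row["center"]) + 73,
             "p": float(np.clip(stats.norm.sf(z), 1e-300, 1.0))}
        )
    for i, row in centers.iterrows():
        z = rng.normal(0, 1)
        bg = _background_position(int(row["center"]), 20_000, _chrom_limit(truth, row["chrom"]))
        rows.append(
            {"construct": f"con_bg_{i}", "chrom": row["chrom"],
             "start": bg - 72, "end": bg + 73,
             "p": float(stats.norm.sf(z))}
        )
    return pd.DataFrame(rows)


def _readout_starr_peaks(truth: PlantedTruth, rng, noise_sd) -> pd.DataFrame:
    """Ranked episomal reporter peaks with output/input fold-change scores."""
    centers = truth.element_centers()
    rows = []
    for i, row in centers.iterrows():
        fold = 1.0 + 8.0 * row["activity"] + rng.normal(0, 4.0 * noise_sd)
        rows.append(
            {"chrom": row["chrom"], "start": int(row["center"]) - 250,
             "end": int(row["center"]) + 250, "name": f"peak_act_{i}", "fold_change": float(max(fold, 0.01))}
        )
    for i, row in centers.iterrows():
        fold = abs(rng.normal(1.0, 0.5))
        bg = _background_position(int(row["center"]), 15_000, _chrom_limit(truth, row["chrom"]))
        rows.append(
            {"chrom": row["chrom"], "start": bg - 250,
             "end": bg + 250, "name": f"peak_bg_{i}", "fold_change": float(fold)}
        )
    return pd.DataFrame(rows)


def _readout_hidra(truth: PlantedTruth, rng, noise_sd) -> pd.DataFrame:
    """Driver elements with RNA/DNA ratios, plus tiled/active region flags."""
    centers = truth.element_centers()
    rows = []
    for i, row in centers.iterrows():
        ratio = 0.8 + 1.5 * row["activity"] + rng.normal(0, 0.5 * noise_sd)
        rows.append(
            {"element": f"dr_{i}", "chrom": row["chrom"],
             "start": int(row["center"]) - 150, "end": int(row["center"]) + 150,
             "rna_dna_ratio": float(max(ratio, 0.01)),
             "tile_start": int(row["center"]) - 2_000, "tile_end": int(row["center"]) + 2_000}
        )
    return pd.DataFrame(rows)


def _readout_crispri(truth: PlantedTruth, rng, noise_sd) -> pd.DataFrame:
    """CRISPRi element-gene regression rows (beta, adjusted p, power, outlier).

    Only elements near a planted gene produce strong negative betas, echoing
    the divergence between episomal activity and endogenous CRISPR effects.
    """
    centers = truth.element_centers()
    genes = truth.genes
    rows = []
    for i, row in centers.iterrows():
        gsub = genes[genes["chrom"] == row["chrom"]]
        if len(gsub) == 0:
            continue
        dist = (gsub["tss"] - row["center"]).abs()
        gi = dist.idxmin()
        near = dist.loc[gi] < 25_000
        eff = row["activity"] if near else 0.0
        beta = -0.5 * eff + rng.normal(0, 0.5 * noise_sd)
        z = 5.0 * eff + rng.normal(0, 4.0 * noise_sd)
        p_adj = float(np.clip(stats.norm.sf(z), 1e-300, 1.0))
        rows.append(
            {"target": f"tg_{i}", "chrom": row["chrom"],
             "start": int(row["center"]) - 150, "end": int(row["center"]) + 150,
             "gene": f"g{gi}", "beta": float(beta), "p_adj": p_adj,
             "outlier_gene": bool(rng.random() < 0.02),
             "power": float(rng.uniform(0.6, 1.0)),
             "fraction_change": float(beta)}
        )
    return pd.DataFrame(rows)
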
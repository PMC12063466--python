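"""Readers and writers for the genomic text formats the pipeline touches.

All internal coordinates are 0-based half-open. Conversions to 1-based
conventions (fixed-step wig) happen only at file boundaries. Signal is stored
densely per base; uncovered positions carry the value 0 ("no signal").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "IntervalSet",
    "SignalTrack",
    "BinarizedTracks",
    "read_chrom_sizes",
    "read_intervals",
    "write_intervals",
    "read_signal_track",
    "write_bedgraph",
    "write_binarized_tracks",
    "read_binarized_tracks",
]


class GenomeIOError(ValueError):
    """Raised on malformed or out-of-bounds genomic records."""


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names/lengths plus the analysis bin grid (default 25 bp)."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int = 25

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise GenomeIOError("chrom_names and chrom_lengths length mismatch")
        if any(l <= 0 for l in self.chrom_lengths):
            raise GenomeIOError("chromosome lengths must be positive")
        if self.bin_size <= 0:
            raise GenomeIOError("bin_size must be positive")
        object.__setattr__(self, "chrom_names", tuple(self.chrom_names))
        object.__setattr__(self, "chrom_lengths", tuple(int(l) for l in self.chrom_lengths))

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise GenomeIOError(f"unknown chromosome {chrom!r}") from None

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.length_of(chrom) / self.bin_size)

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_lengths))

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chrom_names)


_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass
class IntervalSet:
    """A sorted set of 0-based half-open genomic intervals (BED semantics)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        for col in _BED_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan if col == "score" else ("." if col in ("name", "strand") else None)
        df = df[_BED_COLUMNS].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise GenomeIOError(
                f"empty or inverted interval {bad['chrom']}:{bad['start']}-{bad['end']}"
            )
        if (df["start"] < 0).any():
            raise GenomeIOError("negative interval start")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    def validate(self, layout: GenomeLayout) -> "IntervalSet":
        lengths = layout.lengths
        for chrom, end in zip(self.records["chrom"], self.records["end"]):
            if chrom not in lengths:
                raise GenomeIOError(f"interval on unknown chromosome {chrom!r}")
            if end > lengths[chrom]:
                raise GenomeIOError(f"interval ends beyond {chrom} length {lengths[chrom]}")
        return self

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.records[self.records["chrom"] == chrom]

    def coverage_mask(self, chrom: str, length: int) -> np.ndarray:
        """Boolean per-base membership mask for one chromosome."""
        mask = np.zeros(length, dtype=bool)
        for start, end in zip(*(self.for_chrom(chrom)[c].to_numpy() for c in ("start", "end"))):
            mask[start:end] = True
        return mask

    def total_bases(self) -> int:
        # overlap-safe: merge per chromosome first
        total = 0
        for _, grp in self.records.groupby("chrom", sort=False):
            last_end = -1
            for start, end in zip(grp["start"], grp["end"]):
                if start > last_end:
                    total += end - start
                elif end > last_end:
                    total += end - last_end
                last_end = max(last_end, end)
        return total

    @staticmethod
    def from_arrays(chroms, starts, ends, names=None, scores=None, strands=None) -> "IntervalSet":
        df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
        if names is not None:
            df["name"] = names
        if scores is not None:
            df["score"] = scores
        if strands is not None:
            df["strand"] = strands
        return IntervalSet(df)


@dataclass
class SignalTrack:
    """Dense per-base signal; one float array per chromosome."""

    data: dict[str, np.ndarray] = field(default_factory=dict)

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Signal at given 0-based positions; out-of-range positions read 0."""
        arr = self.data[chrom]
        pos = np.asarray(positions, dtype=np.int64)
        ok = (pos >= 0) & (pos < arr.size)
        out = np.zeros(pos.shape, dtype=np.float64)
        out[ok] = arr[pos[ok]]
        return out

    def binned(self, chrom: str, bin_size: int) -> np.ndarray:
        """Mean signal per bin (trailing partial bin averaged over its bases)."""
        arr = self.data[chrom]
        n_bins = math.ceil(arr.size / bin_size)
        padded = np.zeros(n_bins * bin_size)
        padded[: arr.size] = arr
        sums = padded.reshape(n_bins, bin_size).sum(axis=1)
        counts = np.full(n_bins, bin_size, dtype=float)
        if arr.size % bin_size:
            counts[-1] = arr.size % bin_size
        return sums / counts


@dataclass
class BinarizedTracks:
    """Per-cell, per-chromosome 0/1 calls for each expert track.

    Matches the text dialect used by ChromHMM binarized inputs: first line
    ``cell<TAB>chrom``, second line tab-separated track names, then one row of
    tab-separated 0/1 values per genomic bin.
    """

    cell_type: str
    chrom: str
    track_names: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.track_names = tuple(self.track_names)
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[1] != len(self.track_names):
            raise GenomeIOError("matrix shape does not match track names")
        if not np.isin(m, (0, 1)).all():
            raise GenomeIOError("binarized matrix entries must be 0 or 1")
        self.matrix = m.astype(np.uint8)


def read_chrom_sizes(path, bin_size: int = 25) -> GenomeLayout:
    """Read a two-column ``chrom<TAB>length`` file into a GenomeLayout."""
    names, lengths = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise GenomeIOError(f"{path}:{lineno}: expected two tab-separated fields")
            names.append(parts[0])
            lengths.append(int(parts[1]))
    return GenomeLayout(tuple(names), tuple(lengths), bin_size)


def read_intervals(path, layout: GenomeLayout | None = None) -> IntervalSet:
    """Parse a BED3+ file into a sorted, validated IntervalSet."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GenomeIOError(f"{path}:{lineno}: fewer than 3 BED fields")
            try:
                rec = {
                    "chrom": parts[0],
                    "start": int(parts[1]),
                    "end": int(parts[2]),
                }
            except ValueError as exc:
                raise GenomeIOError(f"{path}:{lineno}: {exc}") from None
            if rec["start"] >= rec["end"]:
                raise GenomeIOError(
                    f"{path}:{lineno}: empty interval {rec['chrom']}:{rec['start']}-{rec['end']}"
                )
            if len(parts) > 3:
                rec["name"] = parts[3]
            if len(parts) > 4 and parts[4] not in (".", ""):
                rec["score"] = float(parts[4])
            if len(parts) > 5:
                rec["strand"] = parts[5]
            rows.append(rec)
    iv = IntervalSet(pd.DataFrame(rows, columns=_BED_COLUMNS) if rows else pd.DataFrame(columns=_BED_COLUMNS))
    if layout is not None:
        iv.validate(layout)
    return iv


def write_intervals(intervals: IntervalSet, path) -> None:
    """Emit BED (3-6 columns depending on populated fields)."""
    df = intervals.records
    have_name = df["name"].notna().any()
    have_score = df["score"].notna().any()
    have_strand = df["strand"].notna().any() and (df["strand"] != ".").any() if len(df) else False
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fields = [row.chrom, str(row.start), str(row.end)]
            if have_name or have_score or have_strand:
                fields.append(str(row.name) if pd.notna(row.name) else ".")
            if have_score or have_strand:
                fields.append(f"{row.score:g}" if pd.notna(row.score) else ".")
            if have_strand:
                fields.append(row.strand if pd.notna(row.strand) else ".")
            fh.write("\t".join(fields) + "\n")


def read_signal_track(path, layout: GenomeLayout) -> SignalTrack:
    """Read bedGraph or fixed-step wig into a dense per-base SignalTrack.

    Wig fixedStep starts are 1-based in the file and shifted to 0-based here.
    Overlapping bedGraph records are rejected.
    """
    data = {c: np.zeros(l) for c, l in layout.lengths.items()}
    covered = {c: np.zeros(length, dtype=bool) for c, length in layout.lengths.items()}
    mode = "bedgraph"
    cur_chrom, cur_pos, cur_step, cur_span = None, 0, 1, 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                mode = "wig"
                kv = dict(tok.split("=") for tok in line.split()[1:])
                cur_chrom = kv["chrom"]
                if cur_chrom not in data:
                    raise GenomeIOError(f"{path}:{lineno}: unknown chromosome {cur_chrom!r}")
                cur_pos = int(kv["start"]) - 1  # wig is 1-based
                cur_step = int(kv.get("step", 1))
                cur_span = int(kv.get("span", 1))
                continue
            if mode == "wig":
                value = float(line)
                sl = slice(cur_pos, cur_pos + cur_span)
                data[cur_chrom][sl] = value
                covered[cur_chrom][sl] = True
                cur_pos += cur_step
            else:
                parts = line.split("\t")
                if len(parts) != 4:
                    raise GenomeIOError(f"{path}:{lineno}: expected 4 bedGraph fields")
                chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                if chrom not in data:
                    raise GenomeIOError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if covered[chrom][start:end].any():
                    raise GenomeIOError(f"{path}:{lineno}: overlapping bedGraph records")
                data[chrom][start:end] = value
                covered[chrom][start:end] = True
    return SignalTrack(data)


def write_bedgraph(track: SignalTrack, path, decimals: int = 6) -> None:
    """Emit run-length-merged bedGraph; zero runs are skipped (no signal)."""
    with open(path, "w") as fh:
        for chrom, arr in track.data.items():
            if arr.size == 0:
                continue
            # boundaries where the (rounded) value changes
            vals = np.round(arr, decimals)
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = vals[s]
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.{decimals}f}\n")


def write_binarized_tracks(tracks: BinarizedTracks, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{tracks.cell_type}\t{tracks.chrom}\n")
        fh.write("\t".join(tracks.track_names) + "\n")
        for row in tracks.matrix:
            fh.write("\t".join(str(int(v)) for v in row) + "\n")


def read_binarized_tracks(path) -> BinarizedTracks:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 2:
            raise GenomeIOError(f"{path}: first line must be 'cell<TAB>chrom'")
        cell, chrom = header
        track_names = tuple(fh.readline().rstrip("\n").split("\t"))
        matrix = np.loadtxt(fh, dtype=np.uint8, ndmin=2)
    return BinarizedTracks(cell, chrom, track_names, matrix)
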
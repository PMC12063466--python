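"""Per-locus chromatin feature extraction.

Each locus (a reference nucleotide) is described by 85 features when 12
marks and a 25-label chromatin-state annotation are configured:

* 36 PCA signal features: the 2-kb signal window around the locus, sampled
  every 25 bp (81 values per mark), projected onto each mark's top three
  principal components fitted on training loci;
* 12 center signal values (the raw signal at the reference nucleotide);
* 12 binary peak indicators (peak present at the reference nucleotide);
* 25 one-hot chromatin-state indicators at the reference nucleotide.

All features are standardized to training mean 0 / SD 1; the whole
transform (PCA loadings, centering means, standardizer statistics) is a
function of training loci only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .genome_io import GenomeLayout, IntervalSet, SignalTrack

DEFAULT_WINDOW = 2000
DEFAULT_STEP = 25
DEFAULT_N_PCS = 3
DEFAULT_N_STATES = 25


class FeatureError(ValueError):
    pass


@dataclass
class CellInputs:
    """One cell type's chromatin inputs: signal, peaks, state annotation."""

    cell_type: str
    layout: GenomeLayout
    signals: dict[str, SignalTrack]
    peaks: dict[str, IntervalSet]
    states: IntervalSet
    _peak_masks: dict = field(default_factory=dict, repr=False)
    _state_ids: dict = field(default_factory=dict, repr=False)

    def peak_mask(self, mark: str, chrom: str) -> np.ndarray:
        key = (mark, chrom)
        if key not in self._peak_masks:
            self._peak_masks[key] = self.peaks[mark].coverage_mask(chrom, self.layout.length_of(chrom))
        return self._peak_masks[key]

    def state_ids(self, chrom: str) -> np.ndarray:
        """0-based state index per base; every base must carry a state."""
        if chrom not in self._state_ids:
            length = self.layout.length_of(chrom)
            ids = np.full(length, -1, dtype=np.int8)
            for row in self.states.for_chrom(chrom).itertuples(index=False):
                ids[row.start:row.end] = int(str(row.name).lstrip("SE")) - 1
            if (ids < 0).any():
                pos = int(np.flatnonzero(ids < 0)[0])
                raise FeatureError(f"base {chrom}:{pos} carries no chromatin state")
            self._state_ids[chrom] = ids
        return self._state_ids[chrom]


def window_offsets(width: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP) -> np.ndarray:
    """Signed offsets covering a window centered on the reference nucleotide."""
    if width % step != 0 or (width // step) % 2 != 0:
        raise FeatureError(f"window width {width} must be an even multiple of step {step}")
    return np.arange(-width // 2, width // 2 + 1, step)


def extract_signal_window(track: SignalTrack, chrom: str, ref: int, offsets: np.ndarray) -> np.ndarray:
    """Signal values at ref+offset; positions beyond the chromosome read 0."""
    if chrom not in track.data:
        raise FeatureError(f"unknown chromosome {chrom!r}")
    return track.values_at(chrom, ref + offsets)


def extract_signal_windows(track: SignalTrack, chroms, refs, offsets) -> np.ndarray:
    """Vectorized window extraction for many loci (rows = loci)."""
    refs = np.asarray(refs, dtype=np.int64)
    out = np.empty((refs.size, offsets.size))
    chroms = np.asarray(chroms)
    for chrom in np.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        pos = refs[idx][:, None] + offsets[None, :]
        out[idx] = track.values_at(chrom, pos)
    return out


def fit_mark_pca(train_windows: np.ndarray, n_components: int = DEFAULT_N_PCS):
    """Top principal components of a loci x window signal matrix.

    Returns (loadings (k, w), mean (w,), explained-variance fractions (k,)).
    The sign of each component is fixed by forcing its largest-magnitude
    loading positive, so results are reproducible across backends.
    """
    X = np.asarray(train_windows, dtype=np.float64)
    if X.shape[0] <= n_components:
        raise FeatureError(
            f"need more than {n_components} training loci, got {X.shape[0]}"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    # full SVD for determinism
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    explained = var[:n_components] / total if total > 0 else np.zeros(n_components)
    loadings = vt[:n_components].copy()
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
    return loadings, mean, explained


@dataclass
class FeatureTransform:
    """Fitted feature map: per-mark PCA plus final standardization."""

    mark_names: tuple[str, ...]
    offsets: np.ndarray
    n_pcs: int
    n_states: int
    pca_loadings: dict[str, np.ndarray]   # mark -> (n_pcs, n_offsets)
    pca_means: dict[str, np.ndarray]      # mark -> (n_offsets,)
    explained: dict[str, np.ndarray]      # mark -> (n_pcs,)
    std_mean: np.ndarray | None = None    # (n_features,)
    std_sd: np.ndarray | None = None

    @property
    def feature_names(self) -> list[str]:
        names = []
        for m in self.mark_names:
            names += [f"{m}_PC{k + 1}" for k in range(self.n_pcs)]
        names += [f"{m}_center" for m in self.mark_names]
        names += [f"{m}_peak" for m in self.mark_names]
        names += [f"state_S{k + 1}" for k in range(self.n_states)]
        return names

    @property
    def n_features(self) -> int:
        m = len(self.mark_names)
        return self.n_pcs * m + 2 * m + self.n_states

    def to_json(self, path) -> None:
        obj = {
            "mark_names": list(self.mark_names),
            "offsets": self.offsets.tolist(),
            "n_pcs": self.n_pcs,
            "n_states": self.n_states,
            "pca_loadings": {m: v.tolist() for m, v in self.pca_loadings.items()},
            "pca_means": {m: v.tolist() for m, v in self.pca_means.items()},
            "explained": {m: v.tolist() for m, v in self.explained.items()},
            "std_mean": None if self.std_mean is None else self.std_mean.tolist(),
            "std_sd": None if self.std_sd is None else self.std_sd.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "FeatureTransform":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            mark_names=tuple(obj["mark_names"]),
            offsets=np.asarray(obj["offsets"]),
            n_pcs=obj["n_pcs"],
            n_states=obj["n_states"],
            pca_loadings={m: np.asarray(v) for m, v in obj["pca_loadings"].items()},
            pca_means={m: np.asarray(v) for m, v in obj["pca_means"].items()},
            explained={m: np.asarray(v) for m, v in obj["explained"].items()},
            std_mean=None if obj["std_mean"] is None else np.asarray(obj["std_mean"]),
            std_sd=None if obj["std_sd"] is None else np.asarray(obj["std_sd"]),
        )


def raw_feature_matrix(
    chroms, refs, cell: CellInputs, transform: FeatureTransform
) -> np.ndarray:
    """Unstandardized loci x features matrix in the fixed column order."""
    refs = np.asarray(refs, dtype=np.int64)
    n = refs.size
    m = len(transform.mark_names)
    cols = []
    for mark in transform.mark_names:
        W = extract_signal_windows(cell.signals[mark], chroms, refs, transform.offsets)
        cols.append((W - transform.pca_means[mark]) @ transform.pca_loadings[mark].T)
    center = np.empty((n, m))
    peak = np.empty((n, m))
    chrom_arr = np.asarray(chroms)
    for j, mark in enumerate(transform.mark_names):
        track = cell.signals[mark]
        for chrom in np.unique(chrom_arr):
            idx = np.flatnonzero(chrom_arr == chrom)
            center[idx, j] = track.values_at(chrom, refs[idx])
            peak[idx, j] = cell.peak_mask(mark, chrom)[refs[idx]]
    onehot = np.zeros((n, transform.n_states))
    for chrom in np.unique(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        sid = cell.state_ids(chrom)[refs[idx]]
        onehot[idx, sid] = 1.0
    return np.hstack(cols + [center, peak, onehot])


def fit_standardizer(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column means and SDs on training rows; zero-variance columns get SD 1."""
    if X.shape[0] == 0:
        raise FeatureError("cannot fit standardizer on an empty training set")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mean, sd


def apply_standardizer(transform: FeatureTransform, X: np.ndarray) -> np.ndarray:
    if transform.std_mean is None:
        raise FeatureError("standardizer not fitted")
    return (X - transform.std_mean) / transform.std_sd


def fit_feature_transform(
    chroms,
    refs,
    cell: CellInputs,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    n_pcs: int = DEFAULT_N_PCS,
    n_states: int = DEFAULT_N_STATES,
) -> FeatureTransform:
    """Fit the full feature transform (PCA + standardizer) on training loci."""
    offsets = window_offsets(window, step)
    marks = tuple(sorted(cell.signals))
    loadings, means, explained = {}, {}, {}
    for mark in marks:
        W = extract_signal_windows(cell.signals[mark], chroms, refs, offsets)
        loadings[mark], means[mark], explained[mark] = fit_mark_pca(W, n_pcs)
    tf = FeatureTransform(marks, offsets, n_pcs, n_states, loadings, means, explained)
    raw = raw_feature_matrix(chroms, refs, cell, tf)
    tf.std_mean, tf.std_sd = fit_standardizer(raw)
    return tf


def assemble_features(chroms, refs, cell: CellInputs, transform: FeatureTransform) -> np.ndarray:
    """Standardized loci x 85 feature matrix for arbitrary loci."""
    return apply_standardizer(transform, raw_feature_matrix(chroms, refs, cell, transform))


def drop_edge_loci(chroms, refs, layout: GenomeLayout, margin: int = 1000):
    """Remove training loci within ``margin`` bases of a chromosome end.

    Used for training only; genomewide scoring keeps edge bins and zero-fills
    the out-of-range part of their windows instead.
    """
    refs = np.asarray(refs, dtype=np.int64)
    chrom_arr = np.asarray(chroms)
    keep = np.ones(refs.size, dtype=bool)
    for chrom in np.unique(chrom_arr):
        idx = chrom_arr == chrom
        length = layout.length_of(chrom)
        keep[idx] &= (refs[idx] >= margin) & (refs[idx] < length - margin)
    return chrom_arr[keep], refs[keep], keep
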
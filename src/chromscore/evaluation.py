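"""Held-out-cell-type generalization evaluation and baselines.

The generalization protocol trains one modified model per cell type that
never sees training data from that cell type; a dataset is then scored with
the version excluding its own cell type. On top of the cell-type hold-out,
the genome is spatially partitioned into 5-kb chunks assigned to train/test
with probability 0.75 (3:1), and AUROC is computed on test-chunk loci only,
repeated over seeded partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .experts import ExpertConfig, predict_expert, train_expert
from .features import CellInputs, drop_edge_loci, fit_feature_transform, assemble_features
from .genome_io import GenomeLayout, IntervalSet
from .labels import ACTIVATING, FunctionalDataset
from .tracks import ScoreTrack


class EvaluationError(ValueError):
    pass


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve: P(score_pos > score_neg) + 0.5 P(equal).

    Computed via the rank-sum (Mann-Whitney U) identity with midranks, which
    handles ties exactly.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("AUROC requires both classes")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def spatial_partition(
    layout: GenomeLayout,
    chunk: int = 5_000,
    p_train: float = 0.75,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Assign 5-kb genome chunks to train (True) / test (False) at p_train."""
    if not 0 < p_train < 1:
        raise EvaluationError("p_train must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    out = {}
    for chrom in layout.chrom_names:
        n_chunks = -(-layout.length_of(chrom) // chunk)
        out[chrom] = rng.random(n_chunks) < p_train
    return out


def partition_of_positions(
    assignment: dict[str, np.ndarray], chroms, positions, chunk: int = 5_000
) -> np.ndarray:
    """True where a position falls in a training chunk."""
    chrom_arr = np.asarray(chroms)
    pos = np.asarray(positions, dtype=np.int64)
    out = np.empty(pos.size, dtype=bool)
    for chrom in np.unique(chrom_arr):
        idx = chrom_arr == chrom
        out[idx] = assignment[chrom][pos[idx] // chunk]
    return out


def chromatin_state_baseline(
    train_labels: np.ndarray, train_states: np.ndarray
) -> dict:
    """Map each chromatin state to its mean positive-label fraction in training.

    States unseen in training fall back to the global positive fraction.
    Returns {"per_state": {state: fraction}, "default": global fraction}.
    """
    y = np.asarray(train_labels).astype(bool)
    s = np.asarray(train_states)
    if y.size == 0:
        raise EvaluationError("empty training set")
    per_state = {
        int(state): float(y[s == state].mean()) for state in np.unique(s)
    }
    return {"per_state": per_state, "default": float(y.mean())}


def apply_state_baseline(model: dict, states: np.ndarray) -> np.ndarray:
    return np.array([model["per_state"].get(int(st), model["default"]) for st in states])


def single_mark_baseline(cell: CellInputs, mark: str, chroms, positions) -> np.ndarray:
    """Signal value of one mark at each reference nucleotide."""
    out = np.empty(len(positions))
    chrom_arr = np.asarray(chroms)
    pos = np.asarray(positions, dtype=np.int64)
    for chrom in np.unique(chrom_arr):
        idx = chrom_arr == chrom
        out[idx] = cell.signals[mark].values_at(chrom, pos[idx])
    return out


@dataclass
class EvaluationRun:
    dataset: str
    excluded_cell: str
    rep: int
    method: str
    auroc: float
    contributing_experts: tuple[str, ...] = ()


def heldout_chromscore_eval(
    datasets: list[FunctionalDataset],
    cells: dict[str, CellInputs],
    layout: GenomeLayout,
    n_reps: int = 20,
    chunk: int = 5_000,
    p_train: float = 0.75,
    expert_cfg: ExpertConfig = ExpertConfig(),
    seed: int = 0,
    baselines: bool = True,
) -> pd.DataFrame:
    """Held-out-cell-type ChromScore evaluation over spatial partitions.

    For each evaluation dataset, experts are trained only on datasets from
    *other* cell types (using train-chunk loci in their own cell's chromatin
    inputs), applied to the evaluated dataset's test-chunk loci in the
    evaluated cell's inputs, and averaged into a held-out ChromScore.
    """
    by_cell = {}
    for ds in datasets:
        by_cell.setdefault(ds.cell_type, []).append(ds)
    if len(by_cell) < 2:
        raise EvaluationError("need datasets from at least two cell types")

    rows = []
    for rep in range(n_reps):
        part = spatial_partition(layout, chunk, p_train, seed=seed * 1000 + rep)
        # train one expert per dataset on its train-chunk loci
        fitted = {}
        for ds in datasets:
            chroms = ds.records["chrom"].to_numpy()
            refs = ds.records["ref_pos"].to_numpy(dtype=np.int64)
            in_train = partition_of_positions(part, chroms, refs, chunk)
            cell = cells[ds.cell_type]
            tr_chroms, tr_refs, keep = drop_edge_loci(
                chroms[in_train], refs[in_train], layout
            )
            y_tr = ds.y()[in_train][keep]
            if y_tr.sum() == 0 or (~y_tr).sum() == 0:
                continue
            tf = fit_feature_transform(tr_chroms, tr_refs, cell)
            X_tr = assemble_features(tr_chroms, tr_refs, cell, tf)
            ens = train_expert(
                X_tr, y_tr, expert_cfg, name=ds.name, cell_type=ds.cell_type,
                assay_class=ds.assay_class, feature_names=tuple(tf.feature_names),
            )
            fitted[ds.name] = (ens, tf)

        for ds in datasets:
            others = [
                name for name, (ens, _) in fitted.items() if ens.cell_type != ds.cell_type
            ]
            if not others:
                raise EvaluationError(
                    f"no cross-cell-type experts available for {ds.name}"
                )
            chroms = ds.records["chrom"].to_numpy()
            refs = ds.records["ref_pos"].to_numpy(dtype=np.int64)
            in_test = ~partition_of_positions(part, chroms, refs, chunk)
            y_te = ds.y()[in_test]
            if y_te.sum() == 0 or (~y_te).sum() == 0:
                continue
            eval_cell = cells[ds.cell_type]
            te_chroms, te_refs = chroms[in_test], refs[in_test]
            preds = []
            for name in others:
                ens, tf = fitted[name]
                X_te = assemble_features(te_chroms, te_refs, eval_cell, tf)
                preds.append(predict_expert(ens, X_te))
            held_out_score = np.mean(preds, axis=0)
            rows.append(
                EvaluationRun(ds.name, ds.cell_type, rep, "ChromScore_heldout",
                              auroc(held_out_score, y_te), tuple(others))
            )
            if baselines:
                # chromatin-state baseline fitted on this dataset's train loci
                in_train = ~in_test
                sid_all = np.empty(len(chroms), dtype=np.int64)
                for chrom in np.unique(chroms):
                    idx = chroms == chrom
                    sid_all[idx] = eval_cell.state_ids(chrom)[refs[idx]]
                model = chromatin_state_baseline(ds.y()[in_train], sid_all[in_train])
                rows.append(
                    EvaluationRun(ds.name, ds.cell_type, rep, "chromatin_state",
                                  auroc(apply_state_baseline(model, sid_all[in_test]), y_te))
                )
                for mark in sorted(eval_cell.signals):
                    sig = single_mark_baseline(eval_cell, mark, te_chroms, te_refs)
                    rows.append(
                        EvaluationRun(ds.name, ds.cell_type, rep, f"mark:{mark}",
                                      auroc(sig, y_te))
                    )
    return pd.DataFrame(
        [
            {"dataset": r.dataset, "excluded_cell": r.excluded_cell, "rep": r.rep,
             "method": r.method, "auroc": r.auroc,
             "contributing_experts": ",".join(r.contributing_experts)}
            for r in rows
        ]
    )


def tss_expression_correlation(
    track: ScoreTrack,
    tss: pd.DataFrame,
    rpkm: np.ndarray,
    half_window: int = 12_000,
    step: int = 25,
) -> pd.DataFrame:
    """Pearson r between track scores and log2(RPKM+1) at each offset around TSSs.

    Windows of negative-strand genes are mirrored. ``tss`` columns: chrom,
    tss, strand.
    """
    if len(tss) < 3:
        raise EvaluationError("need at least three genes")
    expr = np.log2(np.asarray(rpkm, dtype=np.float64) + 1.0)
    offsets = np.arange(-half_window, half_window + 1, step)
    vals = np.full((len(tss), offsets.size), np.nan)
    for gi, row in enumerate(tss.itertuples(index=False)):
        pos = row.tss + offsets if row.strand == "+" else row.tss - offsets
        length = track.layout.length_of(row.chrom)
        ok = (pos >= 0) & (pos < length)
        vals[gi, ok] = track.bin_values_at(row.chrom, pos[ok])
    rows = []
    if expr.std() == 0:
        return pd.DataFrame({"offset": offsets, "r": np.nan})
    for oi, off in enumerate(offsets):
        col = vals[:, oi]
        use = ~np.isnan(col)
        if use.sum() < 3 or col[use].std() == 0 or expr[use].std() == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(col[use], expr[use])[0, 1])
        rows.append({"offset": int(off), "r": r})
    return pd.DataFrame(rows)


HIGH_EXPRESSION_LOG2 = 1.0    # log2(RPKM+1) above this: high-expression gene
LOW_EXPRESSION_LOG2 = 0.01    # below this: low-expression gene


def expression_categories(rpkm: np.ndarray) -> np.ndarray:
    """Categorize genes as 'high' / 'low' / 'mid' by log2(RPKM+1) thresholds."""
    lev = np.log2(np.asarray(rpkm, dtype=np.float64) + 1.0)
    return np.where(lev > HIGH_EXPRESSION_LOG2, "high", np.where(lev < LOW_EXPRESSION_LOG2, "low", "mid"))
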
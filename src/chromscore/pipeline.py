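"""Stage-wise pipeline orchestration over the synthetic fixtures.

Stages run in dependency order: simulate -> labels -> experts -> tracks ->
hmm -> enrich -> evaluate. Each stage writes its artifacts plus a manifest
(config digest, seed, output checksums); a rerun with an unchanged config
skips stages whose manifests and outputs are intact. Chromatin inputs are
regenerated deterministically from the fixture seed rather than serialized,
so only derived artifacts live on disk.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import evaluation as ev
from . import labels as lb
from . import scorehmm as shmm
from . import synthetic_fixtures as fx
from . import tracks as tr
from .config import PipelineConfig, stage_up_to_date, write_stage_manifest
from .experts import ExpertConfig, ExpertEnsemble, train_expert
from .features import (
    CellInputs,
    FeatureTransform,
    assemble_features,
    drop_edge_loci,
    fit_feature_transform,
)
from .genome_io import write_intervals

log = logging.getLogger("chromscore")

STAGES = ("simulate", "labels", "experts", "tracks", "hmm", "enrich", "evaluate")

# config sections each stage's digest depends on (cumulative upstream)
_STAGE_SECTIONS = {
    "simulate": ("fixture",),
    "labels": ("fixture", "labels"),
    "experts": ("fixture", "labels", "features", "experts"),
    "tracks": ("fixture", "labels", "features", "experts", "tracks"),
    "hmm": ("fixture", "labels", "features", "experts", "hmm"),
    "enrich": ("fixture", "labels", "features", "experts", "tracks", "hmm"),
    "evaluate": ("fixture", "labels", "features", "experts", "evaluation"),
}


class Pipeline:
    """Orchestrates all stages for one config and output directory."""

    def __init__(self, cfg: PipelineConfig, outdir: str | Path):
        self.cfg = cfg
        self.out = Path(outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self._cells: list[fx.CellFixture] | None = None
        self._blacklist = None
        self._datasets: list[lb.FunctionalDataset] | None = None
        self._experts: dict[str, tuple[ExpertEnsemble, FeatureTransform]] | None = None
        self._tracks: dict[str, dict[str, tr.ScoreTrack]] | None = None

    # -- shared objects -----------------------------------------------------

    @property
    def fixture_config(self) -> fx.FixtureConfig:
        f = self.cfg.fixture
        return fx.FixtureConfig(
            seed=self.cfg.seed,
            n_chroms=f.n_chroms,
            chrom_length=f.chrom_length,
            n_cell_types=f.n_cell_types,
            n_elements=f.n_elements,
            n_repressive=f.n_repressive,
            n_genes=f.n_genes,
            effect=f.effect,
            noise_sd=f.noise_sd,
            bin_size=self.cfg.bin_size,
            schemes=tuple(f.schemes),
        )

    def cells(self) -> list[fx.CellFixture]:
        if self._cells is None:
            self._cells = fx.simulate_all_cells(self.fixture_config)
        return self._cells

    def blacklist(self):
        if self._blacklist is None:
            self._blacklist = fx.make_blacklist(self.fixture_config)
        return self._blacklist

    def cell_inputs(self, cell: fx.CellFixture) -> CellInputs:
        return CellInputs(
            cell.cell_type, self.fixture_config.layout, cell.signals, cell.peaks, cell.states
        )

    # -- stage helpers ------------------------------------------------------

    def _manifest_path(self, stage: str) -> Path:
        return self.out / "manifests" / f"{stage}.json"

    def _maybe_skip(self, stage: str) -> str | None:
        digest = self.cfg.section_digest(*_STAGE_SECTIONS[stage])
        if stage_up_to_date(self._manifest_path(stage), digest, self.out):
            log.info("[%s] up to date, skipping", stage)
            return None
        return digest

    def _finish(self, stage: str, digest: str, outputs: list[Path]) -> None:
        write_stage_manifest(
            self._manifest_path(stage), stage, digest, self.cfg.seed, outputs, self.out
        )
        log.info("[%s] done (%d artifacts)", stage, len(outputs))

    # -- stages -------------------------------------------------------------

    def stage_simulate(self) -> bool:
        digest = self._maybe_skip("simulate")
        if digest is None:
            return False
        layout = self.fixture_config.layout
        outputs = []
        sizes = self.out / "genome.chrom.sizes"
        with open(sizes, "w") as fh:
            for c, l in layout.lengths.items():
                fh.write(f"{c}\t{l}\n")
        outputs.append(sizes)
        bl = self.out / "blacklist.bed"
        write_intervals(self.blacklist(), bl)
        outputs.append(bl)
        for cell in self.cells():
            p = self.out / f"truth_{cell.cell_type}_elements.bed"
            write_intervals(cell.truth.elements, p)
            outputs.append(p)
            p = self.out / f"states_{cell.cell_type}.bed"
            write_intervals(cell.states, p)
            outputs.append(p)
        self._finish("simulate", digest, outputs)
        return True

    def datasets(self) -> list[lb.FunctionalDataset]:
        if self._datasets is not None:
            return self._datasets
        cfg = self.fixture_config
        lc = self.cfg.labels
        layout = cfg.layout
        out = []
        for ci, cell in enumerate(self.cells()):
            truth = cell.truth
            for scheme in cfg.schemes:
                seed = self.cfg.seed * 10_000 + ci * 100 + fx.ASSAY_SCHEMES.index(scheme)
                readout = fx.simulate_assay_readouts(truth, scheme, seed, cfg.noise_sd)
                if scheme == "sharpr":
                    recs = lb.label_sharpr(readout, lc.sharpr_act_thresh, lc.sharpr_rep_thresh)
                    ds = lb.build_dataset(
                        f"{scheme}/{cell.cell_type}", cell.cell_type, "plasmid_mpra",
                        recs, layout=layout,
                    )
                elif scheme == "pvalue":
                    recs = lb.label_pvalue(readout, lc.pvalue_alpha)
                    ds = lb.build_dataset(
                        f"{scheme}/{cell.cell_type}", cell.cell_type, "plasmid_mpra",
                        recs, layout=layout,
                    )
                elif scheme == "starr_peaks":
                    recs = lb.label_top_fraction_peaks(readout, lc.peak_top_fraction)
                    ds = lb.build_dataset(
                        f"{scheme}/{cell.cell_type}", cell.cell_type, "plasmid_starr",
                        recs, layout=layout, blacklist=self.blacklist(),
                        neutral_ratio=lc.neutral_ratio, seed=seed,
                    )
                elif scheme == "hidra":
                    recs = lb.label_hidra(readout, layout, ratio=lc.neutral_ratio, seed=seed)
                    ds = lb.build_dataset(
                        f"{scheme}/{cell.cell_type}", cell.cell_type, "plasmid_starr",
                        recs, layout=layout,
                    )
                else:  # crispri
                    recs = lb.label_crispri(readout, "gasperini", lc.pvalue_alpha)
                    ds = lb.build_dataset(
                        f"{scheme}/{cell.cell_type}", cell.cell_type, "crispr",
                        recs, layout=layout,
                    )
                if ds.n_activating > 0 and ds.n_neutral > 0:
                    out.append(ds)
        self._datasets = out
        return out

    def stage_labels(self) -> bool:
        digest = self._maybe_skip("labels")
        if digest is None:
            return False
        ldir = self.out / "labels"
        ldir.mkdir(exist_ok=True)
        outputs = []
        for ds in self.datasets():
            p = ldir / f"{ds.name.replace('/', '_')}.tsv"
            header = ds.records.assign(
                name=ds.name, cell_type=ds.cell_type, assay_class=ds.assay_class
            )
            header.to_csv(p, sep="\t", index=False)
            outputs.append(p)
        self._finish("labels", digest, outputs)
        return True

    def experts_fitted(self) -> dict[str, tuple[ExpertEnsemble, FeatureTransform]]:
        if self._experts is not None:
            return self._experts
        layout = self.fixture_config.layout
        ecfg = ExpertConfig(
            n_members=self.cfg.experts.n_members, C=self.cfg.experts.C, seed=self.cfg.seed
        )
        cells = {c.cell_type: self.cell_inputs(c) for c in self.cells()}
        fitted = {}
        for ds in self.datasets():
            chroms = ds.records["chrom"].to_numpy()
            refs = ds.records["ref_pos"].to_numpy(dtype=np.int64)
            tr_chroms, tr_refs, keep = drop_edge_loci(chroms, refs, layout)
            y = ds.y()[keep]
            if y.sum() == 0 or (~y).sum() == 0:
                continue
            cell = cells[ds.cell_type]
            tf = fit_feature_transform(
                tr_chroms, tr_refs, cell,
                window=self.cfg.features.window, step=self.cfg.features.step,
                n_pcs=self.cfg.features.n_pcs, n_states=self.cfg.features.n_states,
            )
            X = assemble_features(tr_chroms, tr_refs, cell, tf)
            ens = train_expert(
                X, y, ecfg, name=ds.name, cell_type=ds.cell_type,
                assay_class=ds.assay_class, feature_names=tuple(tf.feature_names),
            )
            fitted[ds.name] = (ens, tf)
        self._experts = fitted
        return fitted

    def stage_experts(self) -> bool:
        digest = self._maybe_skip("experts")
        if digest is None:
            return False
        edir = self.out / "experts"
        edir.mkdir(exist_ok=True)
        outputs = []
        for name, (ens, tf) in self.experts_fitted().items():
            stem = name.replace("/", "_")
            ens.to_json(edir / f"{stem}.ensemble.json")
            tf.to_json(edir / f"{stem}.transform.json")
            outputs += [edir / f"{stem}.ensemble.json", edir / f"{stem}.transform.json"]
        self._finish("experts", digest, outputs)
        return True

    def score_tracks(self) -> dict[str, dict[str, tr.ScoreTrack]]:
        """Per cell type: every expert's genomewide track (experts cross cells)."""
        if self._tracks is not None:
            return self._tracks
        out: dict[str, dict[str, tr.ScoreTrack]] = {}
        for cell in self.cells():
            ci = self.cell_inputs(cell)
            out[cell.cell_type] = {
                name: tr.score_genome(ens, ci, tf)
                for name, (ens, tf) in self.experts_fitted().items()
            }
        self._tracks = out
        return out

    def stage_tracks(self) -> bool:
        digest = self._maybe_skip("tracks")
        if digest is None:
            return False
        tdir = self.out / "tracks"
        tdir.mkdir(exist_ok=True)
        outputs = []
        tc = self.cfg.tracks
        for cell_type, expert_tracks in self.score_tracks().items():
            for name, track in expert_tracks.items():
                p = tdir / f"{cell_type}_{name.replace('/', '_')}.bedgraph"
                tr.write_score_bedgraph(track, p)
                outputs.append(p)
            cs = tr.chromscore(list(expert_tracks.values()))
            p = tdir / f"{cell_type}_ChromScore.bedgraph"
            tr.write_score_bedgraph(cs, p)
            outputs.append(p)
            if len(expert_tracks) > 1:
                qmap = tr.build_quantile_map(
                    expert_tracks, blacklist=self.blacklist(),
                    n_sample=tc.n_normalization_sample, n_bins=tc.n_quantile_bins,
                    seed=self.cfg.seed,
                )
                ncs = tr.normalized_chromscore(qmap, expert_tracks)
                p = tdir / f"{cell_type}_ChromScore_normalized.bedgraph"
                tr.write_score_bedgraph(ncs, p)
                outputs.append(p)
                names, corr = tr.pairwise_track_correlation(
                    expert_tracks, blacklist=self.blacklist(),
                    n_sample=tc.n_correlation_sample, seed=self.cfg.seed,
                )
                p = tdir / f"{cell_type}_expert_correlations.tsv"
                pd.DataFrame(corr, index=names, columns=names).to_csv(p, sep="\t")
                outputs.append(p)
        self._finish("tracks", digest, outputs)
        return True

    def hmm_results(self):
        binarized = []
        for cell_type, expert_tracks in self.score_tracks().items():
            binarized += shmm.binarize_cell(expert_tracks, cell_type, self.cfg.hmm.top_fraction)
        params, trace = shmm.learn_hmm(
            binarized, K=self.cfg.hmm.K, seed=self.cfg.seed,
            n_restarts=self.cfg.hmm.n_restarts, max_iter=self.cfg.hmm.max_iter,
            tol=self.cfg.hmm.tol,
        )
        segs = shmm.decode_segmentation(params, binarized)
        return binarized, params, trace, segs

    def stage_hmm(self) -> bool:
        digest = self._maybe_skip("hmm")
        if digest is None:
            return False
        hdir = self.out / "hmm"
        hdir.mkdir(exist_ok=True)
        outputs = []
        from .genome_io import write_binarized_tracks

        binarized, params, trace, segs = self.hmm_results()
        for b in binarized:
            p = hdir / f"{b.cell_type}_{b.chrom}_binary.txt"
            write_binarized_tracks(b, p)
            outputs.append(p)
        p = hdir / "emissions.tsv"
        pd.DataFrame(params.emission, columns=list(params.track_names),
                     index=[f"E{k+1}" for k in range(params.K)]).to_csv(p, sep="\t")
        outputs.append(p)
        p = hdir / "transitions.tsv"
        pd.DataFrame(params.transition).to_csv(p, sep="\t")
        outputs.append(p)
        order, classes = shmm.order_and_classify_states(params)
        p = hdir / "state_classes.tsv"
        pd.DataFrame({"state": [f"E{k+1}" for k in order], "class": classes}).to_csv(
            p, sep="\t", index=False
        )
        outputs.append(p)
        for cell_type, seg in segs.items():
            p = hdir / f"{cell_type}_segmentation.bed"
            shmm.segmentation_to_bed(seg, p)
            outputs.append(p)
        self._seg_cache = (params, segs)
        self._finish("hmm", digest, outputs)
        return True

    def stage_enrich(self) -> bool:
        digest = self._maybe_skip("enrich")
        if digest is None:
            return False
        edir = self.out / "enrichment"
        edir.mkdir(exist_ok=True)
        outputs = []
        _, _, _, segs = self.hmm_results()
        for cell in self.cells():
            seg = segs[cell.cell_type]
            tab = enr.overlap_fold_enrichment(seg, cell.truth.elements)
            p = edir / f"{cell.cell_type}_element_enrichment.tsv"
            tab.to_csv(p, sep="\t", index=False)
            outputs.append(p)
            cs = tr.chromscore(list(self.score_tracks()[cell.cell_type].values()))
            q = enr.quantile_fold_enrichment(
                cs, {"planted_elements": cell.truth.elements},
                n_quantiles=50, n_sample=20_000, blacklist=self.blacklist(),
                seed=self.cfg.seed,
            )
            p = edir / f"{cell.cell_type}_quantile_enrichment.tsv"
            q.to_csv(p, sep="\t", index=False)
            outputs.append(p)
        self._finish("enrich", digest, outputs)
        return True

    def stage_evaluate(self) -> bool:
        digest = self._maybe_skip("evaluate")
        if digest is None:
            return False
        cells = {c.cell_type: self.cell_inputs(c) for c in self.cells()}
        ecfg = ExpertConfig(
            n_members=self.cfg.experts.n_members, C=self.cfg.experts.C, seed=self.cfg.seed
        )
        table = ev.heldout_chromscore_eval(
            self.datasets(), cells, self.fixture_config.layout,
            n_reps=self.cfg.evaluation.n_reps, chunk=self.cfg.evaluation.chunk,
            p_train=self.cfg.evaluation.p_train, expert_cfg=ecfg, seed=self.cfg.seed,
        )
        p = self.out / "evaluation.tsv"
        table.to_csv(p, sep="\t", index=False)
        self._finish("evaluate", digest, [p])
        return True

    def run(self, stages: tuple[str, ...] = STAGES) -> dict[str, bool]:
        """Run the requested stages in dependency order; returns ran/skipped flags."""
        ran = {}
        for stage in STAGES:
            if stage not in stages:
                continue
            ran[stage] = getattr(self, f"stage_{stage}")()
        return ran


def run_pipeline(cfg: PipelineConfig, outdir, stages: tuple[str, ...] = STAGES) -> dict[str, bool]:
    logging.basicConfig(stream=sys.stderr, format="%(name)s %(message)s")
    return Pipeline(cfg, outdir).run(stages)
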
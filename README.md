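# chromscore

Predicting genomewide regulatory activity from chromatin marks, with
per-assay "expert" classifiers, combined **ChromScore** tracks, and
**ChromScoreHMM**-style genome segmentations.

## The problem

Functional characterization assays — plasmid reporter assays (MPRA,
STARR-seq and variants) and CRISPRi screens — measure whether a DNA sequence
can drive or sustain gene expression, but each assay covers a sliver of the
genome, in one cell type, with its own readout and biases. Chromatin-mark
data (histone modifications, H2A.Z, DNase accessibility) are available
genomewide across a large panel of cell types. This package learns the map
from chromatin-mark features to assay-measured activity and uses it to score
every 25-bp interval of a genome in any cell type with mark data:

1. **Labels.** Each dataset's raw readout is reduced to binary
   *activating* / *neutral* labels at a single *reference nucleotide* per
   tested region, with dataset-specific rules (tiling-score `S_absmax`
   thresholds, p-value cutoffs, top-10%-of-peaks, RNA/DNA ratio > 1, CRISPRi
   regression significance) and 3:1 sampled neutral backgrounds where the
   assay provides no negatives. Repressive regions are excluded.
2. **Features.** Each locus is described by 85 features: for each of 12
   marks, a 2-kb signal window sampled every 25 bp (81 values) is projected
   onto the top 3 training-fitted principal components (36 features), plus
   the raw center signal (12), a peak-presence indicator (12), and a one-hot
   25-label chromatin-state annotation (25). Features are standardized with
   training statistics.
3. **Experts.** One bagging ensemble of 100 L2-penalized logistic
   regressions (C = 1) per dataset, with class weights
   w(activating) = n_neutral, w(neutral) = 3·n_activating — an effective
   activating fraction of exactly 1/4 for any class counts. The ensemble
   prediction is the mean member probability.
4. **Tracks.** Experts are applied at the center nucleotide (13th base) of
   every 25-bp bin; **ChromScore** is the per-bin mean over experts.
   Quantile normalization (1000 rank bins onto a per-rank median reference)
   makes expert score distributions directly comparable.
5. **Segmentation.** Each expert track is binarized at its top-2% threshold;
   a shared K-state (default 15) multivariate-Bernoulli hidden Markov model
   is learned across all cell types jointly (concatenated training, full
   Baum–Welch) and decoded by maximum posterior per bin. States are ordered
   by mean emission and classified as multi-expert / single-expert /
   no-expert.
6. **Evaluation & enrichment.** Overlap, peak-center, cumulative,
   TSS-positional and score-quantile fold enrichments; held-out-cell-type
   generalization AUROC with chromatin-state and single-mark baselines over
   seeded 5-kb spatial train/test partitions.

Because the real inputs are consortium-scale, the package ships a
first-class synthetic-fixtures module: a deterministic mini-genome with
planted regulatory elements, mark-specific signal bumps, peaks, a 25-state
annotation, an excluded-regions list, and assay readouts for all five label
schemes — enough to exercise and test every stage end to end in seconds.

## Worked example

Train two experts on one synthetic cell type, build ChromScore, learn a
3-state segmentation and check that planted elements land in expert states:

```python
import numpy as np
from chromscore import FixtureConfig
from chromscore.synthetic_fixtures import simulate_all_cells, simulate_assay_readouts, make_blacklist
from chromscore import labels as lb
from chromscore.features import CellInputs, fit_feature_transform, assemble_features, drop_edge_loci
from chromscore.experts import ExpertConfig, train_expert
from chromscore.tracks import score_genome, chromscore
from chromscore.scorehmm import binarize_cell, learn_hmm, decode_segmentation, order_and_classify_states
from chromscore.enrichment import overlap_fold_enrichment

cfg = FixtureConfig(seed=1, n_chroms=2, chrom_length=200_000, n_cell_types=2,
                    n_elements=25, n_repressive=8)
cells = simulate_all_cells(cfg)
inputs = {c.cell_type: CellInputs(c.cell_type, cfg.layout, c.signals, c.peaks, c.states)
          for c in cells}

expert_tracks = {}
for scheme, seed in (("sharpr", 7), ("starr_peaks", 8)):
    cell = cells[0]
    readout = simulate_assay_readouts(cell.truth, scheme, seed)
    if scheme == "sharpr":
        ds = lb.build_dataset("sharpr/CT1", "CT1", "plasmid_mpra",
                              lb.label_sharpr(readout), layout=cfg.layout)
    else:
        ds = lb.build_dataset("starr_peaks/CT1", "CT1", "plasmid_starr",
                              lb.label_top_fraction_peaks(readout, frac=0.5),
                              layout=cfg.layout, blacklist=make_blacklist(cfg),
                              neutral_ratio=3, seed=seed)
    chroms = ds.records["chrom"].to_numpy()
    refs = ds.records["ref_pos"].to_numpy(np.int64)
    tc, tr_, keep = drop_edge_loci(chroms, refs, cfg.layout)
    tf = fit_feature_transform(tc, tr_, inputs["CT1"])
    X = assemble_features(tc, tr_, inputs["CT1"], tf)
    ens = train_expert(X, ds.y()[keep], ExpertConfig(n_members=25, seed=2), name=ds.name)
    print(f"{ds.name}: {ds.n_activating} activating / {ds.n_neutral} neutral loci, "
          f"PC1-3 of DNase explain {tf.explained['DNase'].sum():.1%} of window variance")
    expert_tracks[ds.name] = score_genome(ens, inputs["CT1"], tf)

cs = chromscore(list(expert_tracks.values()))
print(f"ChromScore: {cs.layout.total_bins} bins, median {np.median(cs.concatenated()):.3f}, "
      f"top-2% threshold {np.quantile(cs.concatenated(), 0.98):.3f}")

binarized = binarize_cell(expert_tracks, "CT1", q=0.02)
params, trace = learn_hmm(binarized, K=3, seed=0, n_restarts=2, max_iter=60)
order, classes = order_and_classify_states(params)
for k, cls in zip(order, classes):
    print(f"state E{k+1}: emissions {np.round(params.emission[k], 2)} -> {cls}")
seg = decode_segmentation(params, binarized)["CT1"]
tab = overlap_fold_enrichment(seg, cells[0].truth.elements)
print(tab[["state", "genome_pct", "fold"]].round(2).to_string(index=False))
```

Output:

```
sharpr/CT1: 25 activating / 25 neutral loci, PC1-3 of DNase explain 92.6% of window variance
starr_peaks/CT1: 25 activating / 75 neutral loci, PC1-3 of DNase explain 89.9% of window variance
ChromScore: 16000 bins, median 0.000, top-2% threshold 0.738
state E3: emissions [0.41 0.95] -> multi_expert
state E1: emissions [0.64 0.  ] -> unclassified
state E2: emissions [0. 0.] -> no_expert
state  genome_pct  fold
   E1        1.68 13.73
   E2       96.22  0.08
   E3        2.10 33.02
```

Reading this: each expert saw a handful of labeled loci; most of the genome
scores near zero while the top 2% of bins score above 0.74. The learned HMM
finds a state (E3) in which both experts' top predictions co-occur — its
emission vector is (0.41, 0.95) — covering 2.1% of the genome and 33-fold
enriched for the planted regulatory elements, while the no-expert state
carries 96% of the genome and is depleted of them.

The same flow is available from the shell:

```
chromscore run -c config.yaml -o outdir/
```

with per-stage subcommands (`simulate`, `extract-labels`, `train-expert`,
`score-genome`, `normalize`, `binarize`, `learn-hmm`, `segment`, `enrich`,
`evaluate`) and stage manifests that make reruns incremental.

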
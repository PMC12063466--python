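# Methods

## Model overview

The package treats regulatory-activity prediction as supervised binary
classification from chromatin features, followed by unsupervised
segmentation of the resulting score tracks.

**Labels.** Each functional characterization dataset is reduced to records
(chrom, reference nucleotide, activating/neutral, raw value). The reference
nucleotide is the single base taken to represent the region: the center of
the winning 5-bp interval for tiling MPRA scores, the construct/peak center
for p-value and peak schemes, the element midpoint for CRISPRi (midpoint of
an even-length region is `start + floor(len/2)` throughout). Scheme rules:

| scheme | activating | excluded |
|---|---|---|
| tiling scores | `S_absmax > 1` | `S_absmax < -1` (repressive) |
| construct p-values | `p < 0.05` (strict) | — |
| ranked reporter peaks | top `floor(0.10·N)` by fold change; ties at the cutoff all kept | — |
| RNA/DNA ratios | ratio `> 1` (strict) | — |
| CRISPRi | any significant (adj. p < 0.05) element–gene pair after keeping beta < 0, non-outlier rows (one scheme) or pairs with power ≥ 0.8 and negative expression change (the other) | filtered pairs |

`S_absmax` is the signed value at the position of maximum absolute tiling
score. Boundary ties (`p = 0.05`, ratio `= 1`) are neutral: the inequalities
are strict by design, matching the "below"/"above" wording of the labeling
rules. Schemes without measured negatives draw exactly 3 neutral bases per
activating region uniformly from the genome minus the excluded-regions
list; sampled neutrals may coincide with activating loci (only blacklist
exclusion is applied). Loci outside the primary assembly chromosomes are
dropped.

**Features (85 per locus for 12 marks, 25 states).** Signal in a 2-kb
window sampled every 25 bp gives 81 values per mark (972 intermediate
features); per-mark PCA fitted on training loci keeps 3 components, and the
raw center-nucleotide value is retained, so 4 signal features per mark
survive. Peak presence and chromatin state are evaluated at the reference
nucleotide exactly. Fixed column order: 36 PC projections (mark-major), 12
center signals, 12 peak indicators, 25 one-hot states. PCA centers with
training means and does not scale variance (raw signal); component signs
are fixed by making each component's largest-magnitude loading positive, so
results are identical across linear-algebra backends. Standardization to
mean 0 / SD 1 uses training statistics; zero-variance columns pass through
with SD treated as 1. Training loci within 1 kb of a chromosome end are
dropped (window purity); genomewide scoring instead zero-fills the
out-of-chromosome part of edge windows so every bin receives a score.

**Experts.** Per dataset, a bagging ensemble of `n_members = 100`
L2-penalized logistic regressions, `C = 1`, lbfgs with tolerance 1e-6 and
up to 1000 iterations; the intercept is unpenalized. Each member fits a
bootstrap of size N with per-sample weights equal to the class weights
w(activating) = n_neutral, w(neutral) = 3·n_activating, which algebraically
fixes the weighted activating fraction at 1/4 regardless of raw counts — a
deliberate tilt so scores highlight the activating tail rather than being
calibrated to a balanced prior. A bootstrap missing a class is redrawn (up
to 20 times). Member seeds derive from `SeedSequence(base_seed, (member,))`.
The ensemble prediction is the mean member sigmoid.

**Tracks.** Experts score the center (13th, 0-based offset 12) nucleotide
of every 25-bp bin. ChromScore is the per-bin mean over experts. Quantile
normalization: all experts are evaluated at the same random genomic sample
(blacklist-excluded); each expert's sorted sample is paired with the
per-rank median across experts (the reference); values map through 1000
rank-quantile bins (right-closed, ties share the lower bin) onto the mean
reference value of the bin, then monotonicity is enforced by a running
maximum. Out-of-range queries clamp to the extreme bins. Production-scale
sampling defaults in the source are documented as 10 M (normalization) and
500 k (pairwise correlation) positions; the shipped defaults (100 k / 50 k)
are sized to the mini-genome fixtures.

**Segmentation.** Per expert per cell type, the binarization threshold is
the score at ascending-rank index `ceil((1-q)·N)` of all genome bins
(q = 0.02); bins scoring at or above it get a 1, so with distinct scores
exactly `floor(q·N)` bins are set and fully tied tracks degenerate to all
ones. A single multivariate-Bernoulli HMM (emissions conditionally
independent per expert given the state) is learned over all
(cell, chromosome) sequences with shared parameters — the concatenated
approach, giving common states but cell-specific assignments. Full-batch
Baum–Welch, scaled forward/backward; emissions are clamped to
[1e-6, 1−1e-6] inside likelihoods to avoid degenerate zeros. Initialization:
seeded uniform-random emissions in [0.1, 0.9], transitions with 0.9
self-transition mass, uniform initial distribution; 5 restarts keep the
best final log-likelihood; stopping at 200 iterations or relative
log-likelihood change < 1e-4. (The external segmentation tool this mirrors
instead subsamples sequences per iteration and disables the likelihood
criterion; full-batch EM is used here and state identities are therefore
not bit-comparable — recovery is verified on simulated parameters instead.)
Decoding is per-bin maximum posterior (ties to the lowest state index), as
in that tool, not Viterbi. States are ordered by descending mean emission
and classified: multi-expert (≥ 2 emissions ≥ 0.20), single-expert (exactly
one ≥ 0.90, rest < 0.10), no-expert (all < 0.001), else unclassified.

**Enrichment.** Fold enrichment = annotation frequency inside a state ÷
genomewide frequency. Segmentation enrichments count bases under the 25-bp
state assignment (equivalent to bin-resolution counting since states are
constant within bins); peak-center enrichments count single center bases,
optionally multicounting duplicated centers. The cumulative curve orders
states by descending fold; each state contributes genome% × fold (its share
of peak centers), and cumulative shares over cumulative genome% give a
non-increasing curve ending at 1. Positional enrichment samples signed
offsets (±12 kb, 200-bp steps) around stranded anchors, mirroring
negative-strand windows and truncating at chromosome ends. Score-quantile
enrichment assigns sampled positions to 200 score quantiles (ties share the
lower quantile) and compares per-set membership frequency per quantile to
the sample-wide frequency.

**Evaluation.** AUROC uses the midrank Mann–Whitney identity
(= P(score⁺ > score⁻) + ½·P(equal)). Generalization protocol: for a
dataset in cell type c, the evaluated score is the mean over experts from
all *other* cell types only; on top, the genome is partitioned into 5-kb
chunks assigned to training with probability 0.75, experts train on
train-chunk loci, AUROC is computed on test-chunk loci, and the procedure
repeats over seeded partitions (default 20). Baselines: a chromatin-state
score (state ↦ training positive fraction, unseen states ↦ global
fraction) and each single mark's raw signal at the reference nucleotide.
TSS–expression analysis correlates track scores at ±12-kb offsets (25-bp
steps, minus-strand windows mirrored) with log2(RPKM+1); genes are called
high/low expressed at log2(RPKM+1) > 1 / < 0.01. No additional proximity
filtering beyond the spatial chunking is applied between train and test
loci, and no cross-dataset locus exclusion.

## Synthetic fixtures

The generator plants, per synthetic cell type, `n_elements` active elements
(activity ~ U(0.2, 1)) and a disjoint repressively marked set on a
mini-genome (defaults: 2 chromosomes × 500 kb, 40 elements, 3 cell types).
Activating marks (DNase, H3K27ac, H3K9ac, H3K4me1/2/3, H2A.Z) gain a
Gaussian signal bump (SD 300 bp, nucleosome-scale spread; amplitude =
effect × mark weight × activity, effect default 3.0 signal units) over a
baseline of 0.1 with 25-bp-block Gaussian noise (SD 0.25); repressive marks
(H3K27me3, H3K9me3) bump over the repressive set; transcription-associated
marks follow planted gene bodies. Peaks are fixed-threshold calls
(baseline + effect/4) on binned signal; the 25-label state annotation marks
TSS-proximal, strong/weak-enhancer-like, repressed and quiescent regions
consistently with the planted truth. Assay readouts are noisy monotone
functions of activity shaped per scheme; noise scalings are chosen so that
at default noise each readout separates high (> 0.5) from low activity with
AUROC > 0.9 — the regime in which end-to-end recovery tests are meaningful.
CRISPRi readouts give strong effects only to elements within 25 kb of a
planted gene, echoing the episomal-versus-endogenous divergence of real
assays.

What the fixtures do **not** emulate: real signal distributions (no
attempt at quantitative realism), mapping artifacts, assay-specific
sequence biases, copy-number effects, or correlated mark noise. Passing
tests therefore demonstrate correctness of the machinery and recoverability
under the planted model, not expected performance on biological data.
Production-scale headline numbers (held-out AUROC levels, genome coverage
fractions, repeat-class folds, tissue-group correlations) depend on
consortium-scale inputs and are out of desk-scale reach by design.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere internally; wig's 1-based
  convention is converted at the file boundary; bedGraph gaps read as 0.
- Top-fraction tie policy (≥ threshold) is shared by peak labeling and
  binarization: deterministic and order-independent, at the cost of
  occasionally exceeding the nominal fraction under ties.
- Pairwise track correlations treat sample SDs below 1e-12 (relative) as
  zero variance and report missing values.
- Test problem sizes (2×200-kb genomes, 10–25 ensemble members, 1–3
  evaluation repetitions, 20-kb-bin HMM recovery) were chosen so the full
  suite runs in about a minute on one CPU while every stage still operates
  above the degenerate regime; defaults in the library itself keep the
  production values.
- Stage manifests record a digest of exactly the config sections a stage
  depends on plus output checksums; rerunning with an unchanged config is a
  no-op, and changing e.g. the ensemble size reruns experts but not labels.

## Known limitations

- The internal HMM reproduces the external segmentation tool's training
  regime only up to its initialization and sequence-subsampling behavior;
  state *identities* are seed-dependent even though recovered parameters
  and classifications are stable.
- CRISPRi label extraction consumes pre-aggregated per-element regression
  tables; re-deriving empirical p-values from gRNA counts is out of scope.
- bigWig input/output is not implemented (text bedGraph/wig only);
  converters exist for both directions.
- Genome-assembly liftover, mark imputation, and comparisons against
  external genomewide scores are out of scope.
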
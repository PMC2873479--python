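# Methods

This note records the precise definitions implemented in `generank`, the
conventions chosen where the underlying methods are commonly stated loosely,
and what the synthetic-data tests do and do not demonstrate.

## Data model and normalization

An `ExpressionMatrix` is a genes × samples real matrix with unique gene and
sample identifiers and labels coded {+1, −1}; both classes must be non-empty
for any scoring operation. Expression units are whatever the input provides
(log or linear): every score here is invariant to positive per-gene affine
rescaling, and TNoM/MDMR are invariant to any strictly increasing per-gene
transform, so the unit choice only matters for interpretability.

The shared normalization subtracts each gene's mean and divides by its
standard deviation. Conventions:

- **SD convention**: population SD (ddof = 0). The choice only rescales rows
  uniformly and cannot change any ranking, so it is fixed rather than
  exposed.
- **Zero-variance genes** map to all-zero rows instead of erroring: real
  chips contain constant probes and a whole-chip scan must survive them.
  Each scoring method then has an explicit degenerate-gene policy (below).
- Normalization is idempotent and invariant to positive affine maps of a
  row; both properties are tested to 1e-9.

Some upstream pipelines also rescale overall intensity per sample
(per-array). That step is pipeline-specific and is out of scope here: only
the per-gene z-normalization is implemented.

`class_stats` exposes per-class means/SDs under a caller-chosen ddof, since
the scores below deliberately mix conventions.

## Parametric scores

- **SNR**: F = |μ₊ − μ₋| / (σ₊ + σ₋), population SDs. The absolute value is
  used so that genes high in either class rank together; a signed variant
  would split a "top 25" into two directions.
- **t**: Welch two-sample |T| = |μ₊ − μ₋| / √(σ₊²/M₊ + σ₋²/M₋), sample SDs
  (ddof = 1, hence ≥ 2 samples per class). Used purely as a ranking score:
  no p-values, no multiple-testing correction.
- **LSD / Fisher criterion**: F = (μ₊ − μ₋)² / (σ₊² + σ₋²), population SDs.

These are the textbook forms of each statistic; SNR/LSD take the population
convention and t the classical sample convention. Denominators are floored
at ε = 1e-12, so a zero-variance gene with equal class means scores 0 and a
zero-variance separated gene scores Δμ/ε — large, finite, and top-ranked,
which is the correct verdict for a noiseless separator.

## Nonparametric scores

- **TNoM** counts the minimum misclassifications of any threshold rule
  sign(a·x + b) over both orientations. It is computed by one sorted sweep
  over the ≤ s+1 cut positions; equal expression values can never be
  separated by a threshold, so cuts run only between distinct values. The
  score is an integer error count (not normalized by s), bounded by
  min(M₊, M₋).
- **MDMR** sorts samples by expression and counts the minimum adjacent swaps
  to reach either modal sequence (all + first or all − first); this equals
  the smaller of the two strict cross-class inversion counts. Tied values
  can be ordered arbitrarily, so tied pairs contribute no inversion — the
  score is the minimum over tie permutations. Note the asymmetry with TNoM
  on tied data: MDMR's rank model may call a tied gene a perfect split where
  a threshold rule cannot; on continuous expression values the two agree
  exactly (zero-sets coincide; tested on 1000 genes).
- **WEPO** first standardizes each gene by z = (x − μ)/MAD, where MAD is the
  **mean** absolute deviation about the mean (not the median form), then
  punishes each strictly wrong-order cross-class pair by its z-gap
  |zᵢ − zⱼ|, taking the minimum over the two orientations. This z-weighted
  wrong-order pair sum is this package's concrete instantiation of
  "z-scores in the rank-swapping scheme" — the most literal reading, in
  which every swap MDMR would need is charged the z-distance it spans. It is
  a reconstruction, documented as such, not a transcription of the original
  formula. MAD = 0 genes score 0 and are flagged degenerate in the ranking's
  `flags` vector so callers can exclude them.

All three are validated against independent oracles: exhaustive threshold
enumeration (TNoM), breadth-first search over adjacent-swap moves, exhaustive
for every label sequence up to 8 samples (MDMR), and direct pair enumeration
(WEPO).

## RFGS — root-voting over random gene groups

Genes are partitioned uniformly at random into M groups (sizes differing by
at most one; a permutation chunked). For each group, "the most significant
gene" is operationalized as the root a CART tree grown on the group would
choose: the gene whose best single threshold split (midpoints between
consecutive distinct sorted values) minimizes weighted Gini impurity of the
two children. Orientation does not affect a split's impurity, so only cut
positions are enumerated; a constant gene has no valid split and is assigned
the parent impurity, so it can only win a group of constants. Ties go to the
lowest gene index by default (`tie="random"` resolves them with the run
RNG).

Because a gene's best-split impurity does not depend on its group, it is
precomputed once per dataset; a cycle then reduces to a random partition
plus a per-group argmin over precomputed priorities. This makes the
procedure exactly equivalent to building a tree root per group while running
chip-scale (7129 genes, M = 1000, N = 100, 10 runs) in well under a second.

Defaults are the benchmark protocol's values: M = 1000 groups, N = 100
cycles, 10 runs, top-25 report. Each run draws its own RNG stream from one
root seed (runs independent, whole procedure reproducible); the per-cycle
partition keeps M and the balanced sizes fixed. Per run, hit counts conserve
exactly N·M marks. Genes are ranked by **mean hits over runs** (ties by
index); the per-run top-n membership count (how many runs place the gene in
their top n) is reported alongside, as the hit table.

RFGS here is only the random-subset-plus-root idea: no bagging of samples,
no out-of-bag error, no trees below the root.

## SVST — ranking on support-vector samples

A linear soft-margin SVM is fit (via libsvm through scikit-learn) on the
gene-normalized matrix at C = 1, with solver tolerance 1e-7 so KKT conditions
hold to ~1e-4. The dual coefficients classify samples: αᵢ = 0 samples lie
strictly outside the margin and carry no information about the hyperplane;
0 < αᵢ < C samples sit on the margin; αᵢ = C samples violate it. Support
samples are selected with tolerance 1e-6·C on the bounds; the default policy
`all_sv` keeps every αᵢ > 0 (the unqualified "extract support vectors"),
while `unbounded_only` keeps only the on-margin samples for users who want
the strictest reading. SNR is then computed on the retained columns. By
default class statistics are recomputed on the reduced set without
re-normalizing rows (the fit and the scoring see the same values);
`renormalize_subset=True` re-runs the per-gene normalization first. A
`gamma` parameter (1/#genes) is recorded on the model for configuration
fidelity but is inert under the linear kernel.

Tested properties: the exact hand-solved two-sample QP (w = 1, b = 0,
α = ½, ½), dual feasibility and Σαᵢyᵢ = 0, unit margins for unbounded
support vectors, refitting on the support set reproducing (w, b) to 1e-4
relative, and invariance of the ranking to dropping α = 0 samples.

## Evaluation harness

`evaluate_method` runs n_repeats independent random k-fold splits
(default 3 folds, 100 repeats). Folds are stratified by class — unstratified
3-fold on 72 samples can produce single-class validation folds — with sizes
differing by at most one. Per training split the method ranks genes
(`selection_scope="per_fold"`, the default) and a linear SVM with C = 1
("default parameters") is trained on the top-k genes and scored on the
validation fold; accuracy is the fraction of correct validation predictions,
averaged over repeats × folds. The alternative `whole_dataset` scope selects
genes once on all samples; it exists to demonstrate selection bias, and the
test suite asserts the asymmetry: on pure noise, per-fold selection stays at
chance while whole-dataset selection inflates accuracy. Stochastic methods
(RFGS) re-randomize fully per repeat from the repeat's RNG stream.

Report cells render as `mean(lo to hi)` with two-decimal accuracies printed
without a leading zero and 1.00 as `1` — e.g. `.95(.88 to 1)`.

## Synthetic data

The generator plants differentially expressed genes on an i.i.d. Gaussian
background: noise gene values ~ N(baseline, noise_sd²); planted gene j has
its +1-class mean shifted by ±δⱼ·noise_sd. The standard recovery protocol
(`planted_spec`) is 10 planted genes at δ = 2 among 500, with 20+20 samples
— an effect size at which all eight methods should, and do, put ≥ 8 of 10
planted genes in their top 25 across ≥ 90% of seeds. Presets emulate the
shapes of the classic leukemia (7129 × 72, 47/25) and prostate (12600 × 102,
52 tumor coded −1, 50 normal +1) benchmark matrices with 30 planted genes at
δ ∈ [1, 3].

Equal-variance Gaussian noise matches the parametric scores' implicit model;
Student-t noise (unit-variance scaled) and per-gene lognormal variance
jitter are available for robustness checks of the nonparametric scores. The
generator does not model probe-level artifacts, batch effects, correlated
genes, or real microarray noise spectra — so passing recovery tests shows
the methods rank a clean planted signal correctly, not that they are robust
to real-chip pathologies.

## Problem sizes used in tests and the acceptance script

Oracle-equivalence checks run at exhaustive-enumeration scale (≤ 12 samples,
hundreds of genes; all label sequences to s = 8 for MDMR). Recovery and
cross-validation checks use the 500-gene protocol above with 20–50 seeds or
repeats; RFGS recovery inside those tests uses a proportionally scaled
configuration (M = 50, N = 20, 3 runs) so group sizes (~10 genes) match the
chip-scale defaults' regime. The acceptance script's chip-scale benchmark
cell uses the leukemia-shaped preset at 10 repeats. These sizes were chosen
as the smallest at which the distributional claims are stable across seeds.

## Known limitations

- Two classes only; no multi-class labels, no missing-value imputation, no
  probe-to-symbol annotation.
- WEPO's punishment is a documented reconstruction (above).
- RES I/O implements the common expression/call-pair dialect; exotic RES
  variants (scale factors, multi-line headers) are not parsed.
- The evaluation harness reproduces a protocol, not any published accuracy
  table: numbers depend on the data supplied to it.
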
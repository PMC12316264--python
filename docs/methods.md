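# Methods

## Problem and unit of classification

The classification unit is the consecutive same-strand gene pair: for each
contig and each strand independently, genes are sorted by start coordinate
and every adjacent pair in that order is a candidate. Genes on the opposite
strand between the two do not break adjacency — they simply lie inside the
pair's intergenic region (IGR) — which is what makes noncontiguous operons
(co-transcribed pairs separated by an antisense gene) visible to the
classifier at all. Same-strand genes nested inside another gene are still
paired by sorted start order with the IGR clamped to length 0; the same
clamping applies to abutting or overlapping genes. All internal coordinates
are 0-based half-open; GFF3/GTF (1-based inclusive) are converted on read
and write, per-base depth TSVs are 1-based, bedGraph is 0-based half-open.

## Feature representation

Per pair and per RNA-seq sample, three per-base depth segments are taken:
gene 1, IGR, gene 2. For minus-strand pairs the segments are ordered and
reversed into transcription order, so "gene 1" is always the upstream gene
and the position axis runs 5′→3′; this makes the representation
strand-agnostic (a mirrored minus-strand pair produces the identical
tensor), and can be disabled (`reorient_minus=False`) for ablation.

The three segments share 150 output positions, apportioned proportionally
to their base-pair lengths by largest-remainder rounding with a guaranteed
minimum of one position per nonempty segment (an empty IGR gets exactly
zero). Each segment is resampled to its allocated width by area-preserving
binning: output position *j* is the mean of the input over the real
interval [*jL/n*, (*j*+1)*L/n*), fractional base overlaps weighted
accordingly. This operator is deterministic, handles both down- and
up-sampling, preserves a constant exactly, and preserves coverage mass
(the segment mean) — the reasons it was chosen over nearest-neighbour or
Fourier resampling. The concatenated 150-vector is min–max scaled to
[0, 1] per (pair, sample); a constant vector maps to all zeros (degenerate
min = max). Scaling per sample rather than jointly across samples keeps
each sample row comparable regardless of library size, which also removes
any need for library-size normalisation. The scaled vector is then split
into three channels, each zeroed outside its own region, so the channels
are disjoint and sum back to the scaled vector.

Samples are stacked as the six tensor rows. With fewer than six samples the
available rows are tiled cyclically (a one-sample organism fills all six
rows with copies); with more than six, the first six in input order are
used. Tiling keeps row statistics realistic compared with zero-padding.

## Labels

Labels come from a table of experimentally supported operons
(`operon_id → gene ids`; a gene may belong to several overlapping units).
A pair is 1 when some operon contains both genes, 0 when both genes are in
the table but never share an operon, and 2 (unknown) when either gene is
absent — lack of annotation is not evidence of absence, so label-2 pairs
are excluded from training and kept for prediction only. Gene-id matching
is exact string matching on a configurable annotation attribute
(`ID`/`locus_tag`/…), since identifier namespaces differ between
annotations and operon resources.

## Network and training

Each ensemble member maps the (150, 6, 3) tensor through: a 64-filter
convolution with kernel (5, 6) and valid padding, whose kernel spans the
full sample axis, giving a length-146 sequence of local pattern activations
(5,824 trainable parameters, ReLU); an LSTM with 64 units returning the
full hidden sequence (33,024 parameters, gate order i/f/g/o, forget-gate
bias initialised to 1); additive self-attention; dropout 0.3; and a
2-class softmax dense layer (2,050 parameters) trained with categorical
cross-entropy.

The attention block is deliberately pluggable: its contract is
(146, 64) sequence → flat 1024-length context plus per-head weight maps.
The default implementation projects each hidden state through a shared
tanh layer of width 16 and scores it with 16 independent head vectors;
each head softmax-weights the 146 states and pools a 64-length context,
and the 16 contexts concatenate to 1024. Its own parameter count (1,296)
is recorded in the ensemble manifest but is not part of the architectural
contract — only the 1024-length context is, because the dense layer's
size forces it. Attention weights are exposed as (heads, 146) maps for
inspection.

Training uses Adam (learning rate 10⁻³, β₁ = 0.9, β₂ = 0.999), batch size
32, at most 100 epochs. Each member holds out a stratified 10% validation
split (at least one instance per class), monitors validation AUROC each
epoch, stops after 10 epochs without improvement and restores the
best-AUROC weights. Members differ only by their derived random seed
(weight initialisation, split, shuffling, dropout); optional bagging
(`bootstrap=True`) resamples each member's training set. All gradients are
analytic (backprop through time for the LSTM) and verified against central
differences in the test suite; forward, backward and the optimiser are
plain numpy, so a fixed seed reproduces training bit-for-bit.

The ensemble probability is the arithmetic mean of the members' class-1
softmax outputs (permutation-invariant; a one-member ensemble equals its
member). The decision threshold is 0.5, compared with ≥ so that a pair at
exactly 0.5 is called operonic. Prediction records also carry the maximum
member probability as a per-pair confidence ceiling.

## Evaluation conventions

Recall, precision, accuracy and F1 = 2PR/(P+R) are computed from the
confusion counts at the threshold; when a denominator is zero the score is
reported as 0 with an explicit flag rather than NaN. AUROC is the rank
statistic with ties counted 0.5 (computed via scikit-learn, and checked in
the tests against an O(n²) positive-versus-negative comparison oracle to
10⁻¹²); hard 0/1 calls are accepted as scores, which is how call-only
tools are placed on a ROC. When comparing tools on a fixed universe of
pairs, pairs a tool failed to predict are imputed with probability exactly
0.49 and a non-operon call: the pair sits just under the decision boundary,
so the tool is penalised for abstaining while its rank metrics are barely
perturbed. Cross-validation is stratified k-fold (k = 10 by default) with
seeded fold assignment; per-metric summaries report the fold mean and a
90% t-interval, mean ± t₀.₉₅,ₖ₋₁·sd/√k (the interval form was an open
choice; a normal approximation differs negligibly at k = 10). Grid search
is a plain loop over a user-supplied grid ranked by cross-validated AUROC.

## Simulator

The generator emulates the statistical structure the classifier exploits,
not read-level artifacts. Genes are placed in same-strand runs (geometric
run length, mean 6) along one contig, with log-normal gene lengths
(median ≈ 735 bp) and log-normal-minus-offset IGR lengths that produce
occasional abutting genes. Consecutive genes within a run join the same
transcription unit (TU) with probability `operon_fraction` (default 0.61,
matching the positive fraction of curated training compendia). Each TU
draws a gamma expression level (shape 2, mean 50×); all bases of a TU —
genes and internal IGRs alike — share that level, so coverage is
continuous across co-transcribed IGRs. Every gap between consecutive TUs
keeps `gap_depth_ratio` (default 0.1) of the mean flanking level. Per-base
counts are negative-binomial per sample (variance μ + μ²/r, default
r = 10) to emulate RNA-seq overdispersion; r is a knob for easy and hard
regimes. A fraction of within-operon IGRs (default 5%) receives an
inserted antisense gene whose own expression adds on top of the continuing
sense coverage — noncontiguous-operon fixtures.

Unknown labels arise by withholding genes from the emitted operon table.
Because a pair is unknown when *either* gene is missing and adjacent pairs
share genes, pairs cannot be censored independently; withholding each gene
with probability q = 1 − √(1 − u) gives pair-level unknown fraction u in
expectation (default u = 0.49, the unknown share of curated training
data). Generative truth (same-TU membership) is emitted separately and is
never affected by censoring.

Two named regimes bracket the difficulty range. `separable_config` — zero
boundary coverage, low dispersion (r = 50), no censoring — is the
strong-signal condition under which the reduced ensemble should approach
perfect held-out ranking. `null_config` removes the signal entirely:
boundary IGRs keep full coverage, *and* every TU is expressed at exactly
the same level, *and* the genome is single-stranded with inter-run gaps
drawn from the ordinary IGR distribution. The last two choices matter:
with independent per-TU levels, segment means estimated over hundreds of
bases expose whether two flanking genes share a level, and with
alternating strands the cross-run pairs have systematically longer IGRs —
either residue alone pushes a trained classifier detectably above chance.
With all three removed, pair geometry and coverage are exchangeable
between classes and held-out AUROC sits at 0.5 within sampling noise.

What passing on simulated data does **not** show: robustness to mapping
artifacts, strand-specific library protocols, 5′/3′ coverage bias, rRNA
depletion residue, condition-dependent operon structure, or operon tables
whose identifiers need nontrivial mapping onto the annotation. Those enter
only with real data through the same interfaces.

## Problem sizes and numerical choices

The end-to-end checks train reduced ensembles (3 members, ≤15 epochs,
patience 5) on ~650-pair simulated datasets with an 80/20 stratified
held-out split, and the reduced cross-validation harness runs k = 3 folds
of a single member on a ~200-pair dataset — sizes chosen so the full suite
and the acceptance script each run in minutes on one CPU while leaving the
stochastic margins wide. Networks train in float32; gradient checks run in
float64. Resampling uses exact cumulative sums, so identity (L = n) and
constants are reproduced bit-for-bit. Largest-remainder allocation breaks
fractional-part ties by segment order (gene 1, IGR, gene 2); the ≥1
guarantee borrows positions from the largest allocation. Degenerate
inputs: an all-equal 150-vector scales to zeros; an empty IGR contributes
an all-zero channel; empty annotations yield empty pair lists; training
refuses single-class data; AUROC raises on single-class inputs rather than
returning a default.

## Known limitations

* Tracks are unstranded total depth; strand-specific libraries would carry
  extra signal the representation currently averages away.
* The attention block reconstructs a published architecture's printed
  output contract, not its exact internal formulation, which the source
  does not fully specify; accordingly its parameter count is documented
  but not asserted.
* Training is CPU-bound numpy; full-scale ensembles (10 members, 100
  epochs, ~10⁴ pairs) are hours of compute, and no GPU path is provided.
* The simulator writes per-base TSV tracks; for multi-megabase genomes
  these files are large and bedGraph input is preferable.
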
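# Methods

## Problem and model

The package scores candidate RNA modification sites from sequence alone.
A site is a single nucleotide (U for 5-methyluridine, the A of an RRACH
context for N6-methyladenosine) represented by a 41-nt window: 20 nt
upstream, the candidate, 20 nt downstream.  Windows are RNA-alphabet
strings (T is normalized to U on input); minus-strand sites are
reverse-complemented so every window reads 5'→3' on its own strand.

The classifier is a convolutional–recurrent network over the one-hot
window matrix (41 × 4, columns A,C,G,U):

1. **Convolution** — 256 filters of width 10, valid convolution, ReLU.
   Output length 41 − 10 + 1 = 32.  Filters act as motif detectors; their
   weights are the object of the downstream interpretation step.
2. **Max pooling** — window 3, stride 3, remainder dropped: ⌊32/3⌋ = 10
   positions survive.
3. **Bidirectional LSTM** — 128 units per direction over the 10 pooled
   positions, standard cell equations
   (C_p = F_p·C_{p−1} + I_p·tanh(W_C[x_p, H_{p−1}] + b_C)).
4. **Attention pooling** — a learned affine map w scores each BLSTM state,
   α_p = softmax over positions, output A = Σ α_p B_p.  The output lies in
   the per-dimension convex hull of the BLSTM states, which the tests
   assert numerically.
5. **Classifier head** — fully connected 256 with ReLU, dropout (default
   0.3) after the FC layer, one sigmoid output in (0,1).

Training minimizes binary cross-entropy with Adam (default learning rate
1e-3, batch 64).  After every epoch the validation set is scored; early
stopping restores the best-validation-accuracy weights once 20 epochs pass
without improvement (validation AUC available as an alternative stopping
metric).  "Patience" counts epochs, i.e. full passes with a validation
check after each.  One seed controls weight initialization, shuffling and
dropout; training is exactly reproducible.

The whole network, including backpropagation through time, is implemented
in NumPy (float32 in training; the layers are dtype-generic so the unit
tests gradient-check the implementation in float64 against central
differences).  At the default size it trains at a few seconds per epoch
per ~3000 windows on one CPU core.

Hyperparameter search (`tune_hyperparameters`) is a seeded random search
over the five conventional knobs — kernel size, filter count, batch size,
learning rate (log-uniform), dropout — each trial scored by
inner-validation AUC, with the full trial table returned.

## Dataset construction rules

- **Balanced U-centered datasets** (the m5U setting): every experimentally
  mapped site is a positive; negatives are unmodified U positions sampled
  uniformly from the supplied sequences, excluding positive coordinates,
  matched 1:1 (configurable ratio).  N-containing and contig-edge-truncated
  windows are dropped.
- **Consensus-constrained datasets** (the m6A setting): candidate
  negatives are RRACH centers (R = A/G, H = A/C/U, methylated A at pattern
  index 2); candidates overlapping any known modification peak (any overlap
  of the base with the half-open interval) or coinciding with a positive
  are removed; the survivors are sampled per region so 5'UTR/CDS/3'UTR
  counts match the positive proportions by largest-remainder rounding
  (each region within ±1 of the exact quota), at a 1:5 positive:negative
  ratio by default.
- **Region assignment** uses a splice-aware transcript model from GTF/GFF3
  (exon + CDS per transcript; UTRs derived in transcript coordinates).
  When transcripts disagree, priority is CDS > 3'UTR > 5'UTR, ties broken
  by the longest transcript.  This isoform rule is a package choice; no
  convention is universal.
- **Splits** are stratified by label (train/test plus k CV folds, fold
  sizes within 1), serialized with their seed so folds reload exactly.
- Duplicate window sequences from distinct genomic sites are retained by
  default (deduplication is available but off), matching the
  no-additional-filter construction the balanced datasets assume.

## Filter interpretation

For a trained filter of width T = 10 scanning an L = 41 window there are
N = L − T + 1 = 32 activations (pre-pooling, ReLU applied).  Positive-class
windows are scanned; every (window, offset) whose activation is strictly
above the filter's mean activation — the mean over all positions of all
scanned windows — contributes its T-mer to the filter's PWM
(counts + 0.5 pseudocount per base, rows normalized).  The threshold
population and the pseudocount are package choices.

The motif score is
M_s = mean(per-window max activation | positives) − mean(... | negatives),
with a two-sided Mann–Whitney test on the per-window maxima supplying the
p-value (the test is a package choice; only the significance level is
conventional).  The activation-offset histogram localizes where in the
window a filter fires; on planted-motif data its mode tracks the plant
offset (shifted by the filter-to-consensus alignment offset when the
filter learned the motif off-center within its kernel).

PWM clustering: pairwise distance 1 − Spearman correlation between
flattened width × 4 matrices, average-linkage hierarchy, cut at k clusters
or at a height.  "Composition" here means the PWM entries themselves; a
per-motif mononucleotide summary is a coarser alternative reading and is
not the default.

Metagene profiles place each predicted site at its fractional position
within its region on a 5'UTR|CDS|3'UTR axis of length 3; densities are
normalized to integrate to 1 over the axis.

## RBP motif matching

Motifs travel in MEME minimal format (ACGT alphabets are relabeled to U;
rows off unit sum beyond 1e-3 are renormalized with a warning).  Two PWMs
are compared over all gapless offsets with at least 4 overlapping columns;
similarity is the mean per-column Pearson correlation (zero-variance
columns contribute 0 by convention), and the best offset is reported.
Significance is a column-permutation test: the target's position order is
shuffled n_perm times, the best similarity recomputed, and
p = (1 + #{null ≥ observed}) / (1 + n_perm).  Raw p and a per-query
Benjamini–Hochberg q-value are both reported; the conventional cutoff
p < 0.01 flags matches.  MEME export allows running an external
motif-comparison tool on identical inputs when its statistic is preferred.

A property of this null worth knowing: if a motif's columns are affinely
equivalent (e.g. the same base with uniform off-consensus mass at two
positions), column permutations can reproduce perfect short alignments and
the self-match p-value is bounded away from its nominal minimum.  Sharp
motifs with genuinely distinct columns do not have this degeneracy; the
test fixtures are built accordingly.

## Variant scanning

For each SNV (indels skipped and counted), every position within one flank
of the variant that is a U on either allele is scored on the reference and
alternate windows.  Categories, mutually exclusive with precedence
loss > gain > altered:

- **loss** — the center U is replaced and the reference window scores
  ≥ threshold;
- **gain** — the alternate allele creates a center U scoring ≥ threshold,
  or a retained center U crosses the threshold upward;
- **altered** — the center U is retained on both alleles and
  |Δ| ≥ delta_min;
- **none** — otherwise.

Defaults threshold = 0.5 and delta_min = 0.1 are package choices exposed
as flags.  For center-base-change variants only the U-allele's score is
thresholded (a non-U center cannot be a site), which makes allele swapping
map gain ↔ loss exactly and negate Δ.

## Synthetic conditions

The generator emulates the statistical structure the model assumes:
fixed-length windows with a forced center base, positives carrying
consensus motifs at configured offsets with per-position substitution
noise (a noised position is redrawn from the background), negatives pure
background.  The canonical conditions are 41-nt center-U windows,
2000 + 2000, background uniform, one consensus UUCGAAUC planted at fixed
offset 12 (immediately 5' of the center U) with substitution rate 0.1,
seed 42.  The fixed offset makes the activation-position histogram a sharp
localization check; a uniform-offset variant is one parameter away.

What passing on these conditions shows: the optimizer, the architecture
plumbing, the filter-decoding chain and the evaluation stack work end to
end and recover a planted signal through realistic point noise.  What it
does not show: performance on real transcriptomes, where motifs are
degenerate and multiple, composition is skewed, sites cluster by
transcript, and labels are noisy — real-data AUCs cannot be inferred from
the synthetic ones.

## Evaluation

Acc/Sn/Sp at a 0.5 threshold; AUC equals the pairwise rank statistic (ties
half), which the tests verify against a brute-force oracle at 1e-9; AUPR is
step-wise average precision (no linear interpolation).  The classical
benchmark crosses the 12 encodings with seven algorithm families
(AdaBoost, decision tree, gradient boosting, KNN, logistic regression,
random forest, SGD-logistic) — 84 cells.  Each cell reports the best mean
out-of-fold AUC over a small fixed tuning grid per family (recorded in
`DEFAULT_TUNING_GRIDS`), since these predictors are conventionally reported
at their best settings; fully-grown trees on a 4-feature encoding would
otherwise understate the family.

Test problem sizes (250–2000 windows per class, 3–10 folds, reduced-width
networks for module tests, the default architecture with a capped epoch
budget for the end-to-end check) are chosen so the whole suite runs in a
few minutes on one core while still exercising the default architecture at
the canonical 2000+2000 conditions.

## Numerical and degenerate-input conventions

- Feature order is lexicographic over (A,C,G,U); positions 5'→3'.
- Compositional encodings reject ambiguous bases; one-hot emits a zero row
  for N and flags it; dataset builders drop N-containing windows.
- PseDNC ships a standard six-index RNA dinucleotide property table
  (rise, roll, shift, slide, tilt, twist), standardized to zero mean and
  unit variance before use and overridable by the user; λ = 2, w = 0.1 by
  default.  SCPseDNC keeps one squared-difference factor per (tier,
  property), so a single-property table collapses it to PseDNC exactly.
- EIIP constants are shipped configuration defaults (standard published
  values), overridable.
- Pooling drops the remainder (valid pooling); attention softmax is
  max-shifted for stability; sigmoid is evaluated piecewise to avoid
  overflow; BCE clips probabilities at 1e-7.
- PWM comparison tie-breaks equal similarities toward the smaller
  |offset|; cluster distances are clipped at 0 before linkage.

## Known limitations

- Sequence-only: no expression, structure or cell-type information.
- The NumPy trainer is single-device and CPU-bound; it is sized for
  datasets of 1e3–1e5 windows, not 1e7.
- PWM clustering requires equal widths (filter-derived PWMs share the
  kernel width; external motifs of other widths must be aligned first).
- The permutation match statistic is not calibrated against external
  motif-comparison tools; p-values agree in spirit, not numerically.
- Region assignment uses a single anchor transcript per site; quantitative
  isoform-aware assignment is out of scope.
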
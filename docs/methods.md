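# Methods

## Model and procedure

The reduction pipeline treats the 20 standard amino acids as the sample,
each candidate property scale as an explanatory variable, and a binary
water-interaction class as the response. The class variable is pluggable;
the default dichotomy assigns residues with positive Kyte–Doolittle
hydropathy (A, C, F, I, L, M, V) to the hydrophobic class and the remaining
13 to the hydrophilic class. Every report records the scheme used. With
n = 20 fixed samples this is an unusual classification problem: single-trial
out-of-bag (OOB) error is granular (multiples of 5% when all samples are
voted), which is why all error-rate decisions are made on means over
repeated forests rather than on single fits.

### Permutation variable importance

For one forest, each tree t is fit on a stratified bootstrap (each class
resampled with replacement to its own size, so both classes are always
in-bag) of the residues; the samples a tree never saw form its OOB set.
The importance of variable x_i is

VIM(x_i) = (1/ntree) · Σ_t ( err·OOB̃_t − err·OOB_t ),

where err·OOB_t is the tree's misclassification **count** on its intact OOB
samples and err·OOB̃_t the count after permuting x_i's values among those
OOB samples. Counts, not rates, are averaged; the two definitions differ
only by a constant factor when OOB sizes are equal, but the count form is
the one the exact one-tree oracle test pins down. A forest's VIM vector is
therefore noisy (OOB sets hold ~7 residues); the reported score is the mean
over `n_trials` independent forests, with sd, median and rank alongside.

Tree induction uses scikit-learn's `DecisionTreeClassifier`; the ensemble,
bootstrap, OOB bookkeeping, permutation and importance aggregation are
implemented here, because library permutation importances average accuracy
differences under their own bootstrap contract and would not expose the
count-level quantity defined above.

### Selection stages

1. **Completeness.** Property records with a missing value for any residue
   are dropped before table construction (`to_index_table` reports them).
2. **Correlation pruning** (threshold 0.85 on Pearson |r| over the 20
   values). Greedy backward elimination: repeatedly locate the pair with
   the highest |r| above threshold and drop the member with the larger mean
   |r| against all remaining properties (ties to the lexicographically
   larger accession). Deterministic, idempotent, and biased toward keeping
   the member that decorrelates the remaining set fastest — note this can
   keep the noisier member of a redundant group, which is material for the
   planted-recovery experiment below.
3. **VIM ranking.** Properties with mean VIM ≤ 0 over the trials are
   dropped; the rest are ordered by decreasing mean (ties by accession).
4. **Nested forward selection.** For prefix sizes k = 1, 2, … the mean OOB
   error percentage over `trials_per_step` forests on the first k
   properties is computed; selection stops just before the first step whose
   mean exceeds `threshold_pct`, keeping that prefix. If even k = 1 exceeds
   the threshold an `EmptySelectionError` carries the diagnostic curve. The
   package default threshold is 2.0%, the operating point for the shipped
   8-property table; it applies to the across-trial mean, which is
   fractional even though single-trial errors move in 5% steps.

A forest's OOB error aggregates per-sample majority votes over the trees
for which the sample was OOB (vote ties go to the lexicographically smaller
class; samples never OOB are excluded from the denominator and are rare
beyond a few dozen trees).

### Reproducibility

All randomness flows from one root seed through
`numpy.random.SeedSequence.spawn`, giving each trial, tree, bootstrap and
permutation an independent, reproducible stream. Identical configuration
and seed give bit-identical reports; this is asserted by test.

## The packaged reduced table

`load_raaindex()` returns the shipped 8-property × 20-residue table
(`data/raaindex.tsv`), the published product of this pipeline applied to a
full property-database snapshot. It is shipped verbatim and treated as
authoritative even where its values may differ from current database
entries for the same accessions. Two conflicting published description sets
exist for these eight accessions; both are shipped
(`data/raaindex_annotations.tsv`) without adjudication. Reproducing the
snapshot-dependent stage counts (544 → 531 → 283 → 93 → 8) of the original
derivation is explicitly out of scope: the pipeline's correctness is
established on planted synthetic tables instead.

## Encoding

`extract_block` removes alignment columns whose gap fraction exceeds
`max_gap_fraction` (default 0.0: strictly gap-free, since homologous blocks
are defined as the columns shared by all sequences). If a tolerance is
allowed, residual gaps are imputed by the column's majority residue and
logged. `encode_bpp` concatenates property rows N→C (L residues × m
properties); `encode_binary8` uses the 8-bit big-endian expansion of each
residue's ordinal (0–19) in the canonical residue order. No published bit
assignment exists for the 8-bit convention; the ordinal code was chosen
because it is injective, trivially decodable, and dimension-matched to the
8-property table, making variance comparisons dimension-fair. The bit table
is exported (`BINARY8_TABLE`) so alternatives can be swapped in. A
sliding-window fragment mode exists (`fragment_alignment`, CLI `--window`)
but is off by default; whole blocks are the primary unit.

## PCA and scheme comparison

Covariance (center-only) PCA: columns are mean-centered, never scaled,
because binary lattices contain exactly constant columns for which
unit-variance scaling is undefined; constant columns are dropped and
listed. Implementation is the SVD of the centered matrix; variance
fractions are eigenvalues of the sample covariance over their trace, and
the test suite checks them against an independent dense eigendecomposition.
Eigenvector signs follow a fixed convention (largest-|loading| entry
positive) so scores are platform-stable. Because the convention is
center-only, variance percentages are dominated by large-scale columns
(e.g. the polarity-scale property spans 0–52 while others span ~±5); a
correlation-convention PCA would give different percentages. This is one
reason encoding-comparison results are reported as a direction (property
coding ≥ binary coding) rather than as particular percentages.

## Synthetic generators

`gen_index_table` plants ground truth: informative columns are
`label_gap · 1[class] + N(0, 1)` (so `label_gap` is the class-mean
separation in within-class sd units), redundant columns add Gaussian noise
scaled for a target theoretical correlation with their parent, and noise
columns are label-independent N(0, 1). Defaults (5 informative, 2 copies
each at r ≈ 0.9, 50 noise, gap 2 sd) emulate a redundant, multicollinear
property database at a realistic effect size — a 2-sd gap leaves ~16%
single-variable Bayes error, so no single property is clean.

`gen_family_alignment` draws, per family, a consensus sequence and mutates
each site i.i.d. with probability `divergence`. In `property_structured`
mode the consensus residues are drawn by a softmax over negative distance
to a family anchor in standardized property space (anchor scale
`between_family_shift`, default 2.0), and substitutions by a softmax over
negative property-space distance from the original residue (temperature
default 1.0); `uniform_random` mode is the structure-free control. Default
scale, 4 families × 70 sequences × 28 columns, mirrors a typical
enzyme-family block dataset. The generator deliberately omits phylogenetic
tree structure, indel processes, and site-rate heterogeneity: passing tests
show the pipeline behaves correctly when its assumptions hold, not that
real alignments satisfy those assumptions.

## Problem sizes and calibrated expectations in tests

Forest sizes in tests are scaled relative to the package defaults
(ntree = 500, 1000 ranking trials, 100 nested trials per step):

- **Planted recovery** runs the full pipeline on 50 generator seeds with
  100 ranking trials of 25 trees and 8 nested trials per step. 100 trials
  put the standard error of a mean VIM near 0.005, enough to resolve the
  weakest planted representatives (true mean VIM ≈ 0.02) against the
  mean > 0 retention rule.
- Recovery is scored per planted **signal group** (an informative column or
  any of its r ≈ 0.9 redundant copies): pruning at 0.85 removes members of
  every such group by design, and the greedy rule preferentially drops the
  parent, so demanding the literal `informative` column would test the
  pruning tiebreak, not signal recovery.
- The nested threshold for this experiment is the **no-information rate**
  (majority-class error, 7/20 = 35%): with a 2-sd gap the 2% operating
  default is unattainable by construction for small prefixes (single-
  variable Bayes error ≈ 16%), so the principled bound is "reject prefixes
  that classify no better than guessing".
- **Noise calibration** redraws the table on every one of 1000 trials. With
  only 20 samples a *fixed* noise column has non-vanishing accidental
  association with the labels, so its VIM converges to a nonzero
  draw-specific value; only under redrawing is the Monte-Carlo mean of a
  pure-noise VIM zero, and the test asserts it lies within 3·SEM of zero.
- **Scheme comparison** uses the generator defaults over 50 seeds and
  asserts the direction (property ≥ binary PC1+PC2 fraction) in ≥ 90% of
  seeds.

## Known limitations

- The pipeline is specialized to binary classification over the 20 fixed
  residue samples; it is not a general-purpose feature selector.
- The nested stage uses one fixed ranking; re-ranking within steps (a
  known variant of nested forest selection) is not implemented.
- The minimum-variance point of the ranked VIM curve is reported for
  diagnostics only; the operative retention rule is mean VIM > 0.
- Percentages from the PCA comparison depend on the centering convention
  and on column scales; only their ordering across schemes is a stable
  claim.
- The AAindex parser handles the single-residue (AAindex1) dialect only and
  rejects pair-substitution matrices with a clear error.
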
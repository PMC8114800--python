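# Methods

## Model

The classifier is a fuzzy decision tree over a linguistically fuzzified
table. Its parts, in pipeline order:

**Fuzzy database (equalized universe).** For attribute *j* with observed
range [minⱼ, maxⱼ] and set count k, the triangular membership functions have
peaks bᵢ = minⱼ + (i−1)(maxⱼ − minⱼ)/(k−1), i = 1..k, with each interior
triangle's feet at its neighbours' peaks and shoulder triangles at the ends
(a₁ = b₁, c_k = b_k). Peaks are computed from the closed formula in double
precision, never by repeated addition, so partitions are bit-reproducible.
Consequences used throughout: memberships sum to 1 everywhere on the closed
universe, at most two (adjacent) sets are active at any point, and adjacent
sets cross at exactly 0.5 midway between peaks. The shoulder choice at the
ends is the unique one preserving the partition of unity on the closed
universe. Integer-valued attributes are fuzzified exactly like continuous
ones. Constant attributes are excluded with a warning: the construction is
undefined for them and they carry no class information.

**Fuzzification.** A cell is replaced by the label of its
maximum-membership set. At an exact 0.5 crossing the left (lower-indexed)
label is chosen; a random choice would be admissible but breaks
reproducibility, so the standardisation is fixed and a `tie_break:
left|right` switch exists for sensitivity checks. The fuzzy database is
built from the *full* dataset and the whole table is fuzzified before any
train/test split — the protocol this package reproduces does exactly that.
A leakage-free alternative (`universe="train"`: per-fold databases from
training rows only, test values clamped) is provided for methodological
comparison and is not the default. Values outside the universe — possible
only in inference on new raw data — are clamped to the universe first;
clamping is the minimal total extension of the in-sample behaviour.

**Tree induction.** Classic ID3: Shannon entropy in bits, information gain
as the selection criterion, a branch for *every* label of the chosen
attribute's partition (not only the labels present in the node's subset),
recursion until class purity or attribute exhaustion. Empty branches become
leaves predicting the parent node's majority class, which makes crisp
inference total. Gain ties are broken by attribute column order (first
wins); equal-count leaf classes by the lexicographically smallest label.
Both tie-breaks are arbitrary but deterministic. No pruning, gain threshold
or minimum node size is applied by default (`min_support` exists, default 1
= off, purely for experimentation). Induction runs on integer-coded numpy
arrays with bincount-based gain computation; the public
`information_gain`/`class_entropy` functions are the readable pandas
equivalents and the test suite checks the two routes against each other and
against an independent brute-force oracle.

**Rules and inference.** One rule per leaf (antecedents = path conditions in
root-to-leaf order); the rules partition the linguistic input space, so
every complete label assignment matches exactly one rule. Rule confidence is
leaf purity — the fraction of covered training rows with the consequent
class; the notion of a per-rule "confidence degree" is not pinned down in
the source material, so it is implemented as this purity and used only for
tie-breaking, while the compatibility degree (below) is what ranks rules at
prediction time. Crisp inference (the default, and what the evaluation
protocol uses, since its test instances are already linguistic) traverses
the tree. Soft inference evaluates each rule's compatibility degree with a
raw numeric instance — the minimum of the antecedent membership degrees
(product available via `tnorm`) — and predicts the class of the
highest-compatibility rule, with ties broken by higher confidence, fewer
antecedents, then extraction order. If every rule scores 0 (only possible
after clamping pathologies; the partition of unity forbids it in-universe)
the training majority class is returned with a warning.

## Evaluation protocol

Repeated stratified 10-fold cross-validation: one *run* shuffles rows into
stratified folds under its own seed (per-fold class counts within 1 of
proportionality), trains on 9 folds, tests on the held-out fold, and scores
the run as the mean of its fold accuracies. Ten runs under consecutive
derived seeds give the reported mean and the SD (sample SD, n−1). Macro
metrics are computed per run from the run's pooled confusion matrix and
averaged over runs; a class never predicted gets precision 0 rather than
being dropped, keeping the macro mean total and conservative. Because the
run-mean-vs-pooled distinction is ambiguous in the source protocol, both
`accuracy` (mean of runs) and `accuracy_pooled` are reported.

The plain-ID3 baseline runs the identical protocol (same folds, so the
t-test is paired) with raw values treated as categorical labels; it refuses
real-valued data with an explicit error, mirroring the "method does not
support the classification" entries of the original comparison. The t-test
defaults to paired mode with df = n_runs − 1 = 9 — the protocol it
reproduces describes an "independent means" test yet quotes df = 9, and the
paired reading is the one consistent with that df; the pooled equal-variance
mode (df = 2n − 2) is available. Zero-variance differences are reported as
t = ±∞, p = 0 (nonzero mean) or t = 0, p = 1 (all-zero), with a degeneracy
flag. Stratification is on by default (`stratified=False` available): the
source protocol says only "10-fold", and stratified folds stabilise the
small-sample case.

## Synthetic data

The generator emulates the structure the method assumes: class-conditional
continuous features concentrated near fuzzy-set peaks. Defaults, chosen once
as the recovery-experiment conditions used across tests and the acceptance
script: 4 attributes on a [0, 10] universe, k = 3, 500 rows, two classes
("case"/"control") drawn 50/50, planted decision-list rules on the first two
attributes (`attr1 IS low → case`, else `attr2 IS high → case`, else
control), Gaussian noise sd = 0.1 × peak spacing (= 0.5 here), values
clamped to the universe. A row is generated class-first (respecting the
balance), then a label cell uniformly among that class's cells, then values
around the cell's peaks. Keeping the planted concept on a two-attribute
subspace makes it exactly representable by an unpruned tree, so recovery is
a sharp test rather than a bias-variance lottery. At this noise level a
value mislabels only if its noise exceeds half the peak spacing (5 sd,
probability ≈ 6×10⁻⁷), so the Bayes accuracy of the generated problem is
≈ 1 and the ≥ 0.95 recovery bar leaves honest room for fold-to-fold
variation.

What the generator does *not* emulate: correlated attributes, class overlap
in feature space, label noise, missing-not-at-random patterns, and the heavy
tails of real laboratory measurements. Passing recovery tests therefore
demonstrates the pipeline's correctness, not clinical-grade accuracy on real
cohorts.

A second generator writes a *synthetic* file in the Wisconsin-original
dialect (699 rows, ID column, nine 1–10 integer attributes with
class-conditional means, class coded 2/4, exactly 16 rows carrying the "?"
missing marker, 458/241 class split) so that the listwise-deletion contract
(699 → 683) and the fuzzy-vs-plain-ID3 comparison can be exercised without
downloading anything. It is a stand-in with the same shape and dialect, not
the real dataset; accuracies measured on it are not comparable to published
numbers on the real file.

## Numerical and design notes

- Entropy uses log₂ with the 0·log 0 = 0 convention; gain is base-invariant
  for argmax purposes anyway.
- Membership evaluation handles the shoulder cases a = b and b = c without
  division by zero; membership is exactly 1 at a peak and exactly 0 at and
  beyond the feet.
- The vectorised table fuzzifier assigns labels by locating values among the
  0.5-crossing midpoints (searchsorted), which is equivalent to per-cell
  argmax including the tie rule; the equivalence is tested.
- Fold assignment, the generator and every CLI entry point take explicit
  integer seeds; repeated runs derive consecutive seeds from the base seed.
- Problem sizes in the tests and the acceptance script (up to 500-row
  tables, 200 null replicates of 120 rows, 100 replicates in the script)
  were chosen to give stable Monte-Carlo estimates while keeping a full run
  in the low minutes on a single core.

## Known limitations

- k is configuration, not a fitted quantity: the best set count in 2–10 is
  left to empirical testing or domain knowledge, and no auto-selection is
  attempted.
- Unpruned trees overfit noisy data; the CV protocol measures this but
  nothing counteracts it (no pruning by design).
- The equalized-universe bounds come from observed extremes, so a single
  outlier stretches every band of its attribute.
- The full-dataset fuzzification default leaks the test rows' minima/maxima
  into training folds; that is faithful to the protocol being reproduced,
  and `universe="train"` quantifies the effect.
- Non-numeric predictive columns are rejected rather than passed through as
  categories; the class column is never fuzzified.
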
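# Methods

## The model

`genofold` classifies binary-labeled tabular data with a soft-margin SVM
whose kernel function is not chosen from a menu but *evolved*. The search
space is a small typed expression language over the two feature vectors a
kernel compares:

- terminals: `x`, `y` (the two d-dimensional inputs);
- operators: `+_v`, `-_v` (elementwise, vector-valued, scalars broadcast),
  `+_s`, `-_s` (reduce both operands to scalars, then add/subtract), and
  `*_s` (inner product on two vectors, otherwise the product of
  reductions), where a vector reduces by summing its components.

The root value is reduced to a scalar, so every expression is a real-valued
kernel K(x, y). The language contains the linear kernel as the single
expression `*_s(x, y)`, and products of reductions reach polynomial-like
kernels such as `<x, y>^2`, which is what lets evolution discover
feature-interaction structure that the linear kernel cannot represent.

### Genotype

An expression tree is stored as a *linear chromosome*: an array of genes,
each a (symbol, link) pairing. Operator genes link to the 1-based positions
of their two children (`l.r`), terminal genes link to themselves. The
package lays chromosomes out in breadth-first order, which makes the
genotype-phenotype map a bijection on BFS-laid-out chromosomes:
`decode . encode = id` on trees and `encode . decode = id` on valid
chromosomes. Validity requires forward-only links, every non-root position
referenced exactly once, and one more terminal than operators — properties
the constructor enforces, so invalid genotypes cannot circulate.

### Evaluation semantics (a design choice)

The operator subscripts (`_v` vector, `_s` scalar) do not by themselves fix
how mixed scalar/vector operands combine. We chose the reduce-based table
above because it (a) makes every expression well-typed with no runtime
failures other than overflow, (b) reproduces the standard linear kernel
exactly, and (c) keeps hand evaluation simple (the worked example
`*_s(-_s(+_v(y, x), x), x)` at x=(1,2), y=(3,4) gives 21: elementwise sum
(4,6); 10 - 3 = 7; 7 * 3 = 21). Overflow is reported — a non-finite Gram
entry invalidates the whole kernel (fitness 0) — never clamped, so
pathological genotypes are eliminated rather than disguised.

### Gram computation

A naive Gram computation evaluates the tree once per sample pair,
O(n m) tree walks of O(d) work per node. Instead the package propagates,
for each tree node, an *affine representation* a·x + b·y + c whose
coefficients are fields over the (n, m) pair grid. Every operator maps to
O(n m) arithmetic on those fields (inner products expand over precomputed
row sums, squared norms and the matrix product A Bᵀ), which is
algebraically identical to entrywise evaluation but independent of d per
node. The entrywise evaluator is retained and the test suite checks the
two routes agree to 1e-10 on random expressions; for the linear chromosome
the Gram equals X Xᵀ to 1e-12.

### Indefinite-kernel repair

Evolved expressions need not be symmetric (e.g. `-_s(x, y)`) or positive
semidefinite, while the SVM solver assumes both. Before training, the
training Gram is symmetrized, (K + Kᵀ)/2, and by default *clipped*:
eigendecomposed with negative eigenvalues zeroed (a Cholesky fast path
skips the eigendecomposition when the matrix is already PD). Clipping is
idempotent and leaves PSD matrices unchanged; `symmetrize`-only repair is
available. Rectangular test-vs-train blocks are used as computed (after the
shared scale factor below); only the square training block is clipped.

### Kernel scale convention

A kernel's overall scale is arbitrary — rescaling K is equivalent to
rescaling the SVM cost C — but evolved Grams span many orders of magnitude,
which both stalls the solver and makes a fixed C mean different things for
different candidates. All evolved kernels are therefore trained at *unit
mean-|diagonal| scale*: the symmetrized training Gram is divided by the
mean absolute diagonal entry (falling back to the mean absolute entry for
degenerate diagonals) and the test block shares the same factor. An
optional cosine normalization K'_ij = K_ij / sqrt(K_ii K_jj) exists (off by
default) and is refused when any diagonal entry is non-positive. A
safety cap of 10^6 solver iterations guards against residual pathological
cases.

## The evolutionary search

- **Initialization**: `population_size` (default 50) random trees by the
  grow method, symbols uniform over the combined pool, depth <= `max_depth`
  (default 4).
- **Fitness**: mean stratified `cv_folds`-fold (default 5) CV accuracy of a
  precomputed-kernel SVM (cost C, default 1.0) on the repaired, scaled
  Gram. Invalid or constant Grams score 0. Fold assignment is fixed per
  run, so fitness is deterministic and cacheable by chromosome text.
- **Selection**: roulette wheel (probability fitness_i / sum fitness;
  uniform when all are zero).
- **Variation**: mutation only, no crossover. Per gene with probability
  `mutation_rate` (default 0.5) the symbol is replaced by a uniformly drawn
  *different* symbol of the same class (operator/terminal); links never
  change, so every mutant is valid by construction. An optional
  subtree-regeneration mutation exists behind a flag, off by default.
- **Elitism**: the single best individual is copied unchanged (default 1),
  making the best-fitness trajectory non-decreasing.
- **Stopping**: `max_generations` (default 20), with an optional
  no-improvement early stop.
- **Tie-breaking**: equal fitness prefers lower complexity (operator
  count), then earlier discovery — a mild parsimony pressure that also
  makes ordering deterministic.

Runs are bit-reproducible for a fixed seed: one `numpy` generator drives
initialization, selection and mutation, and everything downstream is
deterministic.

## Data pipeline

The expected input is a clinical screening survey: gender (M/F), integer
age, thirteen symptom/history columns coded YES=2/NO=1, and a YES/NO
outcome. Preprocessing drops rows containing missing cells (counted and
reported), encodes gender M=2/F=1 and the outcome YES=+1/NO=-1 (both
configurable conventions chosen for consistency with the 1/2 symptom
coding), and z-score standardizes every column with moments fitted on the
training rows only — inside each CV fold in the comparison harness — so no
scaling information leaks from held-out data. Zero-variance columns are
kept as constant zero and reported.

Class imbalance handling is exposed but off by default: `balance=weights`
(class-weighted SVM losses) or `balance=oversample` (random minority
oversampling of the training split only).

## Synthetic generator

The generator emulates the survey structure at its default study
conditions: n=309, benign (NO) fraction 39/309, age ~ N(62.6, 8) rounded
and truncated to [21, 90] (truncation bounds are plumbing to keep ages
plausible), and per-feature class-conditional YES-prevalences whose
marginals sit near the survey's typical feature means (about 1.5 for most
symptoms, 1.8 for fatigue, 1.6 for coughing and shortness of breath).

Features are drawn from the mixture marginal; the outcome is then drawn
from a logistic model whose per-feature weights are the naive-Bayes
log-odds implied by the class-conditional prevalences, plus — when
`nonlinear_pair` is set — an XOR interaction term (+effect_size when the
two answers disagree) in the log-odds. The intercept is calibrated by root
finding so the marginal NO fraction matches `benign_fraction`. This single
mechanism realizes both the class-conditional prevalence specification and
the interaction clause coherently, and is deterministic per seed.

**XOR benchmark conditions.** The planted-interaction benchmark
(`GeneratorConfig.xor_benchmark`) uses balanced classes, all linear
prevalence separations removed, and effect_size 3.0 on the
(ANXIETY, PEER_PRESSURE) pair. Balance is essential: at the default 87/13
imbalance the Bayes-optimal classifier for a pure XOR signal is the
majority rule, so accuracy could not distinguish interaction-aware kernels
from constant predictors.

**What the generator does not emulate**: real surveys correlate symptoms
with each other and with age/smoking beyond what class-conditional
independence plus one interaction captures, and real missingness is not
random. Passing tests on synthetic data therefore demonstrate that the
machinery recovers the signals it plants — linear signals via prevalence
separation, interaction signals via XOR — not that any particular accuracy
will transfer to a given real dataset.

## Evaluation protocol

`compare_kernels` uses one shared stratified outer 5-fold assignment for
all models. Per outer fold, the evolutionary search runs on the training
portion only (its fitness CV is nested inside that portion, preventing
selection bias from inflating held-out estimates), and the evolved kernel
plus linear, RBF (gamma = 1/(d·var), the "scale" convention) and polynomial
(degree 3, coef0 0) baselines — all at C = 1.0 by default, logged in every
report — are scored on the held-out portion. Reported are accuracy, ROC
AUC (Mann-Whitney with ties at 1/2; absent for single-class folds), MSE of
0/1-coded predictions (equal to 1 - accuracy for hard predictions; the only
coding that keeps MSE in [0, 1] alongside accuracy), confusion counts, and
mean +- sample SD (n-1) across folds.

The seeded-benchmark protocol used by the test suite and the acceptance
script evolves on one outer training fold (80%) per seed and compares the
evolved kernel with the linear baseline on that fold's held-out 20% — five
evolutions across five seeds rather than twenty-five, which keeps the
benchmark at minutes of CPU while still scoring on data the search never
saw.

## Problem sizes and numerical choices

- Benchmarks and the acceptance script use n about 300 with population 50
  and 20 generations (roughly 1,000 fitness evaluations per search, each a
  5-fold SVM fit on about 190-250 samples).
- Constant-Gram detection threshold: peak-to-peak < 1e-12.
- Clip repair floor: minimum eigenvalue >= -1e-8 after repair.
- Fitness cache keyed by chromosome text (exact), safe because fitness is
  deterministic within a run.
- Degenerate inputs: single-class labels are rejected up front; a class
  smaller than k rejects the fold request; all-null tables are rejected
  with the count of dropped rows.

## Known limitations

- Symbol-only mutation never changes tree shapes after initialization, so
  structural diversity is fixed by the initial population (subtree mutation
  exists behind a flag for users who want it).
- Eigenvalue clipping of the training Gram with unprojected test blocks is
  a pragmatic standard treatment of indefinite kernels, not an exact
  theory; strongly indefinite evolved kernels may be scored conservatively.
- The accuracy comparison inherits the usual caveat for imbalanced data;
  the package reports AUC and the confusion matrix alongside accuracy, and
  offers balancing switches, rather than adjudicating a single best metric.
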
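# Methods

## Problem and model

The package selects feature subsets from a numeric table of M samples by N
features with one ordered class label per sample (the motivating case:
quantitative features of neonatal EEG epochs graded normal / mild /
moderate / major). Selection is two-staged: a convex screen first discards
features with no marginal association to the grade, then a population
metaheuristic searches the screened subspace for a small subset that
maximizes a wrapper criterion.

### Stage 1: elastic-net screen

Features are z-scored with training-split statistics (sample sd, ddof = 1;
constant columns map to zeros rather than raising, so degenerate fixtures
pass through). The screen fits

    (1/2M) Σ (y − ŷ)² + λ(α‖β‖₁ + (1−α)/2‖β‖₂²)

via coordinate descent (sklearn's `ElasticNet`, whose objective is exactly
this) and retains features with |β| > 1e−8. The ordered grades enter as
numeric responses y ∈ {0..K−1} by default — they are ordered severities, so
an ordinal-numeric encoding preserves the monotone structure; a
one-vs-rest mode (one indicator regression per class, retain if any
coefficient is nonzero) is available for unordered labels. Hyperparameters:
the shipped operating point is α = 0.7, λ = 0.00178; alternatively a grid
search (defaults: α ∈ {0.1, 0.5, 0.7, 0.9, 0.95, 0.99, 1}, 50 log-spaced λ
in [1e−5, 1e2]) maximizes mean held-out performance over 5 folds (negative
squared error in ordinal mode, accuracy in one-vs-rest), breaking ties
toward the stronger penalty (larger λ, then larger α) for parsimony.
During the grid scan, non-converged fits at extreme grid points score with
their approximate solution; the final fit is strict and raises on
non-convergence.

### Stage 2: crow search

Fitness of a binary mask over the L_t screened features:

    fitness = Acc + w(1 − L_s/L_t),  w = 0.2 (must lie in [0, 1])

Acc is KNN accuracy (k = 5, Euclidean) under stratified 10-fold CV with the
fold assignment drawn once per run and reused for every mask — fitness is
then a pure, memoized function of the mask, which is what makes an
exhaustive-enumeration optimum well defined for oracle testing. The fold
count degrades to the smallest class size when a class is tiny (logged).
KNN tie rules are explicit and deterministic: distance ties resolve to the
lower training index (stable sort), vote ties to the nearest neighbour's
class. A per-feature squared-difference tensor (skipped above ~60M entries
in favour of on-the-fly Gram computation, same result) reduces each mask
evaluation to a sum over selected slices.

Each of P = 10 crows holds a continuous position in
[lower_bound, upper_bound] = [0, 1] per coordinate; its mask is read off by
thresholding at 0.4 — the same operation that creates initial positions
from uniform draws, giving initial selection density 0.6. Per iteration
(kMax = 30): crows are sorted by descending position fitness; one chaotic
value C₁ = 0.7, Cₖ₊₁ = sin(πCₖ) is shared by all crows; each crow computes
its dynamic awareness probability

    DAP = AP_min + (AP_max − AP_min) · fitness / min_fitness_seen,

clipped into [AP_min, AP_max] = [0.1, 0.9] (with positive fitness the ratio
is ≥ 1, so unclipped the local branch would never fire — the clip keeps
both branches reachable). If Cₖ ≥ DAP the crow flies locally,
v = X + Cₖ·fl·(M − X) with fl = 2, clipped to the bounds, toward the best
memory among its assigned neighbours — the six crows ranked immediately
below it (wrapping modulo P; for P ≤ 7 this is simply all other crows) plus
a random crow and that crow's three-chain. Otherwise it moves globally:
the new position keeps the crow's memory values on a random 80% of
coordinates and re-draws the remaining ⌈0.2·L_t⌉ uniformly. Memories
update on strict improvement only; empty masks are repaired by raising one
random coordinate to the upper bound. The classic baseline replaces the
chaotic value with a per-crow uniform draw, uses a constant awareness
probability and a uniformly random neighbour, and jumps to a fresh uniform
random position in its global branch.

Two representation choices deserve emphasis, because the coarser
alternatives are degenerate. With strictly 0/1 positions, the local flight
leaves every coordinate on which the crow and the followed memory agree
unchanged, and a union-style global move can only add features — no
trajectory can shrink a mask below its initial ~60% density, which
contradicts both the sparsity reward and the intended behaviour of the
method. Keeping positions continuous between evaluations lets flights
cross the threshold gradually in both directions, and reading the global
move as a *partition* (80% experience, 20% exploration) gives the search
its only feature-removal operator. On the ten-feature oracle problem this
changes exact-optimum attainment from 0/20 runs to 20/20.

### Evaluation

Selected masks are graded by an SVM with RBF kernel at fixed penalty
C = 0.1 (a deliberately strong regularizer, kept constant so comparisons
across masks are like-for-like), kernel width γ = 1/(d · pooled variance)
with d the selected count, one-vs-rest decision scores for K > 2.
Normalization is always fit on the training split only. The report carries
the confusion matrix, per-class TP/FP/TN/FN, accuracy, precision/recall/F1
per class with support-weighted (headline) and macro averages, and
one-vs-rest ROC (trapezoidal area) and PR (step-wise average precision)
curves, macro-averaged across the classes present in the truth; micro
averages are also computed. A cross-validated curve variant (stratified
10-fold on the training split) accompanies the held-out numbers.

## Synthetic data

The generator emits Gaussian class-conditional tables: informative columns
are unit-sd noise plus a class mean, with adjacent ordered-class means
spaced `effect_size` sd apart along a random ±1 direction per column (for
two classes this is exactly the between-class mean separation); redundant
columns are positive combinations of two sign-aligned informative parents,
normalized to unit sd plus a residual of sd `redundancy_noise` (alignment
prevents the class signal cancelling, so redundant columns keep |corr| >
0.5 with a parent at residual ≤ 0.5); noise columns are standard normal;
column order is shuffled; labels follow the requested proportions by
largest-remainder apportionment, with optional label flips. The EEG-shaped
preset fixes the 289 schema names over the 11-pair bipolar montage, the
84:54:12:18 cohort imbalance (168 samples), and plants ten informative
columns at fixed positions concentrated in temporo-occipital wavelet
energies, beta-band amplitude, delta-band range-EEG and burst statistics.
By default it adds no redundant block — the recovery benchmark asks
whether planted features are recovered, and redundant proxies make
"recovery" ill-defined because the screen may legitimately keep a proxy
instead of the original.

What the generator does *not* emulate: temporal structure, channel
correlation, non-Gaussian tails, annotator noise, or any signal-level EEG
property. Passing recovery tests shows the pipeline's machinery is sound
under a favourable, well-specified signal model — not that it will recover
biomarkers from real EEG.

## Benchmarks and problem sizes

Two desk-scale protocols (in `crowfs.experiments`) exercise everything:

* **Oracle**: 10 features (3 informative, spacing 2 sd, n = 200, four
  classes); all 1023 masks are enumerated with the fixed-fold fitness to
  obtain the exact optimum, then 20 paired improved/classic runs at the
  default configuration are scored against it. The improved search attains
  the exact optimum in ≈19–20/20 runs; the classic baseline in ≈8/20 with a
  lower mean best fitness.
* **Recovery**: the EEG-shaped cohort, split 70/30 stratified; selection on
  the training split with the fixed screening operating point; ten
  replicates. Typical outcomes: the screen keeps ~110 of 289 features
  including all ten planted; the selected mask holds ~47–49% of the search
  space with mean planted recall ≈ 0.86–0.89.

These sizes keep the full suite and the acceptance script to seconds on a
single CPU while remaining large enough for the statistical assertions.

## Known limitations

* **Search budget vs. mask cleanliness.** With P = 10 and kMax = 30 the
  search performs ~310 fitness evaluations. On a ~110-feature space the
  20%-of-L_t exploration step (~22 coordinates) couples noise-removal with
  informative-removal: proposals that drop many noise features usually drop
  planted ones too and are rejected, so the best mask stalls near 50%
  density well short of the planted-only optimum (observed: fitness ~1.0
  vs. the planted-optimum ~1.18). Consequently the selected mask still
  carries enough noise columns that the C = 0.1 SVM performs no better on
  it than on all features on the synthetic cohort — the selected-vs-all
  comparison ties rather than strictly improving. Longer runs, larger
  populations, or a finer exploration step would close this gap, but the
  defaults are kept at the reference configuration.
* **Dynamic awareness is clipped-constant in practice.** Because fitness is
  positive and the denominator is the historical minimum, the raw DAP
  saturates; after clipping, the local branch fires only on iterations with
  a high chaotic value. The global (exploration) branch therefore does most
  of the work.
* **Fold-quantized fitness.** With ~120 training samples, CV accuracy moves
  in steps of roughly 0.008; fitness differences below that are noise, which
  bounds how finely the sparsity reward (w/L_t per feature) can discriminate
  on large search spaces.
* The elastic-net retained-count monotonicity in λ holds empirically on
  well-conditioned data and is asserted in tests, but coordinate descent
  offers no formal guarantee of support monotonicity.
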
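# Methods

## The model

`rankbag` implements an adaptive, multi-objective ensemble classifier for
binary problems, aimed at high-dimensional tabular data (microarray,
proteomic spectra) where no single algorithm is reliably best and where the
"best" algorithm even changes with the performance measure used to judge it.

Training combines bagging with weighted rank aggregation:

1. **Initialization.** Choose N bootstrap rounds, M component algorithms
   A_1..A_M, and K performance measures with positive weights w_1..w_K.
2. **Sampling.** Draw a simple random sample of size n with replacement.
   The draw is rejected and redrawn wholesale until every class appears
   in-bag *and* the out-of-bag (OOB) complement is non-empty (a draw with no
   OOB rows cannot be scored; one missing a class cannot fit every
   component).  Rejection is bounded (default 1000 attempts) and fails
   loudly for degenerate class frequencies.
3. **Classification.** Fit all M components on the in-bag rows.
4. **Performance assessment.** Predict the OOB rows and compute the K
   measures, producing K ordered lists L_1..L_K of the M algorithms
   (best first).
5. **Rank aggregation.** The round's winner is the leader of the ordering
   delta* minimizing

       Phi(delta) = sum_{i=1..K} w_i * d(delta, L_i),

   with d either the Spearman footrule distance (sum of absolute rank
   displacements) or the Kendall tau distance (discordant pairs).  The
   winner's already-fitted in-bag model is stored; it is *not* refitted on
   the full data, because prediction is defined over the bootstrap-fitted
   local winners.

Prediction runs a sample through the N stored winners and takes the
majority vote; the class probability is the vote proportion
P(C = c | x) = (1/N) sum_i I(yhat_i = c), a multiple of 1/N.  Exact vote
ties (only possible for even N) break deterministically toward the
configured positive class; the default N = 101 is odd precisely so this is
rare.

Permutation variable importance adapts the random-forest recipe to the
heterogeneous ensemble: for member i with OOB rows O_i,
I_m = (1/N) sum_i (e_i^(m) - e_i), where e_i is the member's OOB
misclassification error and e_i^(m) the same error after shuffling feature
m within O_i (one permutation per member-feature pair by default;
`n_repeats` averages several).

The **greedy baseline** answers "why not just pick the best algorithm
once?": it k-fold cross-validates all M components (stratified folds,
default k = 10), averages each measure across folds, performs a single rank
aggregation, and refits the lone winner on all training data.  It shares
every building block with the ensemble but does no model averaging, and is
the comparison target for the claim that local per-bootstrap selection
generalizes better.

## Rank aggregation internals

Distances are used unnormalized (integer counts); the weights carry all
scaling.  Input lists must be strict orderings over one identifier set —
score ties are resolved upstream (see below), which keeps the distance
definitions textbook-exact.

* **Brute force** (default, M <= 8): all M! orderings are evaluated
  vectorized against precomputed rank/pair-sign tables (8! = 40320 rows,
  ~1 ms per aggregation).  Ties in Phi break toward the lexicographically
  first identifier sequence, making results reproducible across runs.
* **Cross-entropy** (any M): permutations are sampled from a
  position-by-item probability matrix, re-estimated each iteration from the
  elite fraction and blended with weight `smoothing` on the new estimate.
  Defaults: sample size 50M, elite fraction 0.1, smoothing 0.7, stop after
  15 stagnant iterations, hard cap 200 (a cap exit is flagged
  `converged=False`).
* **Genetic** (any M): tournament selection (size 2), order crossover,
  swap mutation (rate 0.1), elitism of one, population 20M, at most 200
  generations with a 30-generation stagnation stop.

Both stochastic optimizers seed their candidate pool with the input lists
themselves, so a single-list problem returns that list exactly, and both are
deterministic given a seed.  On every random problem with M <= 6 exercised
in the tests they attain the exact brute-force minimum.

## Performance measures

Measures follow the standard 2x2 confusion layout with cells a (true
positive), b (false positive), c (false negative), d (true negative):
accuracy (a+d)/n, sensitivity a/(a+c), specificity d/(b+d).  A zero
denominator yields NaN — an explicit "undefined" flag, never a silent 0.
AUC is the tie-corrected Mann-Whitney rank statistic, required because
vote-proportion scores tie heavily on the grid {0, 1/N, ..., 1}.

Two conventions must be explicit because they change reported numbers:

* **Positive class.** Defaults to the numerically/lexicographically larger
  label; sensitivity and specificity swap under the opposite convention.
  Overridable everywhere.
* **Ties and undefined scores in ranking.** Exact score ties are broken by
  a seeded random shuffle within the tied block — a fixed preference order
  would systematically favor one algorithm over thousands of bootstrap
  rounds.  A measure undefined for the whole round (e.g. sensitivity when
  the OOB set happens to hold no positives) is dropped from that round's
  aggregation rather than imputed; with the all-classes-in-bag resampling
  rule this is rare.  The ensemble's AUC-as-a-measure option uses each
  adapter's continuous decision score.

## Component adapters

Core fitting delegates to scikit-learn; the adapter layer contributes the
uniform contract (fit / predict / decision_score), the reducer+classifier
compositions, and error discipline (failures carry the spec id so the
ensemble can exclude a component from one round without aborting a run).

Defaults mirror the classical R-implementation defaults of these methods:
SVM cost 1, gamma 1/p, polynomial degree 3, coef0 0; random forest 500
trees with mtry = sqrt(p); PLR is l1-penalized logistic regression with the
penalty chosen by internal 3-fold cross-validation on the training part
only; PCA/PLS reducers use 5 components, clipped to the available rank with
a warning.  PLS "as a classifier" fits a PLS regression on 0/1-coded labels
and thresholds predictions at 0.5, the midpoint of the coded values —
the simplest reading consistent with PLS's dual use as reducer and
classifier.  QDA applies a small covariance shrinkage (reg_param = 1e-3)
because the SVD-based solver otherwise rejects the near-singular
within-class covariances that routinely arise on reduced scores, which
classical QDA routines fitted without complaint; genuinely singular inputs
(features >= smallest class) still raise a named error.  Exact decision
thresholds per family are documented in the adapter module and verified by
a predict/score consistency test.

Reducers are fitted strictly on the training rows of the call; the fitted
projection is stored and reapplied to prediction-time rows, so no test
information can leak into the projection (checked by an outlier-injection
test).

## Synthetic designs

* **threenorm(n, d, a)** — class 0 is an equal mixture of N(+a·1, I) and
  N(-a·1, I); class 1 is N((a,-a,a,-a,...), I); a = 2/sqrt(d) by default
  (the benchmark's standard definition; the parameter is exposed so other
  readings can be forced), balanced n/2 per class.  Hard and nearly
  symmetric: unsupervised variance directions (PCA) are useless, supervised
  projections (PLS) help, the Bayes error is substantial.
* **simulated_microarray(n_cases, n_controls, d, frac_informative, delta)**
  — d independent unit-variance probes; the first d·frac_informative are
  N(delta, 1) in cases vs N(0, 1) in controls, the rest N(0, 1) in both.
  Defaults d = 5000, 10% informative, delta = 0.3, 50 cases + 50 controls
  per set (per-class sizes are parameters and are recorded in the
  metadata).  delta = 0 gives an exchangeable null where any classifier's
  expected accuracy is 0.5.
* **dominant_spec_toy(n)** — two features, classes separated on feature 0
  with a margin of 1, feature 1 pure noise; the oracle fixture for
  selection and importance tests.

All generators are deterministic given a seed and record regeneration
metadata.  What they deliberately do **not** model: probe-probe
correlation, batch effects, heavy-tailed intensities, class imbalance.
Passing benchmarks therefore demonstrate the selection/aggregation
machinery under clean independence assumptions, not robustness to real
microarray artifacts.

## Benchmarks and problem sizes

The benchmark harness repeats, R times: draw fresh train and test sets,
fit every method on train, score accuracy / sensitivity / specificity /
AUC on test; it reports means and standard errors sd/sqrt(R).  Replicates
are seeded via `SeedSequence.spawn`, so parallel and serial runs produce
identical tables, and a method failing in one replicate drops only that
replicate (with bookkeeping of the effective R).

Full-scale settings are the package defaults: threenorm with R = 100
replicates, N = 101 bootstraps, eight components (SVM, PLR, RF, PLS+RF,
PLS+LDA, PLS+QDA, PCA+LDA, PLS); simulated microarray with R = 50 and the
four SVM kernels.  The test suite and the acceptance script run a
**desk-scale** configuration chosen to keep a full verification cycle on a
single CPU within minutes rather than hours: R = 20, N = 51, and 100-tree
forests for the RF-based members (the adapter default remains 500).  At
these sizes the across-replicate standard error of a table mean is about
0.01-0.02, comfortably inside the comparison tolerances used in the tests;
the forest reduction changes RF means by far less than that.

The external-CV runner wraps any method in outer stratified k-fold CV; for
the ensemble the inner selection is its bootstrap/OOB loop, giving the
double-CV layout used for real datasets.  Real-data workflows (a breast
cancer blood-expression set and an ovarian SELDI proteomics set) ship as
documented config templates under `examples/workflows/` only — they require
external downloads and hours of compute, and are not exercised by tests.

## Numerical and design choices

* Identifier sequences must be mutually orderable (strings in practice);
  lexicographic order defines all deterministic tie-breaks.
* The ensemble stores, per round, the full OOB score table of all surviving
  components — selection is auditable after the fact.
* Brute-force aggregation is the default (M <= 8 covers both standard
  component sets); the run metadata records distance and optimizer.
* Ensemble AUC is computed from vote proportions, the only probability the
  voting model defines; averaging member decision scores is a plausible
  alternative but mixes incomparable scales across heterogeneous winners.
* `draw_bootstrap`'s empty-OOB redraw has probability ~(1 - 1/n)^n per
  draw of not being needed — effectively never at realistic n.

## Known limitations

Binary classification only (multi-class voting and class-specific
accuracies are out of scope); simple random bootstrap sampling only
(class-prevalence-aware sampling would need reweighted aggregation);
Brier score and kappa are not offered as measures; model bundles are joblib
pickles and are not portable across major scikit-learn versions.

Component defaults have drifted across software generations, and some
historical comparisons depend on exactly the weak spots of old defaults: in
our benchmarks a default radial SVM is a genuinely competitive component on
the threenorm design (an observation we confirmed against the classical R
implementation as well), and the greedy baseline only underperforms the
ensemble when some component is *erratically* bad across folds — a
degenerate-but-consistently-bad component is filtered out by both
selectors equally.  The ensemble's value proposition is robustness when the
component roster is heterogeneous in quality, not a guaranteed strict win
over single-winner selection.
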
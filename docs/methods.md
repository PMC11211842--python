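# Methods

`branchscore` estimates branch support for maximum-likelihood phylogenies
as a supervised classification problem.  Every internal branch of an
inferred tree induces a bipartition (split) of the taxon set; on simulated
data we know whether that split occurs in the generating ("true") tree, so
a classifier can be trained to predict, from properties of the alignment
and the inferred tree alone, the probability that a split is correct.  The
calibrated classifier output is the branch support: a value of 0.7 is
meant to be right about 70% of the time.

## Classification framing

For an alignment with inferred unrooted binary tree T on n taxa, the
classification units are the n − 3 nontrivial bipartitions of T.  The
label is y = 1 iff the bipartition occurs in the generating tree.
Confusion-matrix metrics use the cutoff C = 0.5 with a strict inequality
(support > C ⇒ predicted correct).  Discrimination is summarized by AUC,
MCC, FPR, FNR and F1; calibration by the expected calibration error (ECE)
over 30 equal-width bins of [0, 1], with empty bins contributing zero.

## Synthetic data generator

Training data are simulated, because only simulation provides labels.
Each replicate is a (true tree, substitution model, alignment) triple:

* **Topology and node times** follow a Yule process (uniform random
  joins, exponential epoch durations, unit birth rate).  Clock-like
  branch lengths are then broken by per-branch lognormal rate noise
  (σ = 0.4) and rescaled so the total tree divergence hits a target drawn
  log-uniformly from [0.5, 20] substitutions/site.  This emulates the
  spread of divergences seen in empirically derived tree databases while
  remaining fully self-contained; it does not reproduce any particular
  empirical distribution of tree shapes, so absolute metric values can
  shift relative to models trained on database-derived trees.
* **Substitution models** are GTR+Γ: exchangeabilities log-uniform on
  [0.25, 4] (normalized to unit mean), base frequencies Dirichlet(20),
  gamma shape α log-uniform on [0.25, 4] with four discrete categories
  (mean of equal-probability bins), proportion of invariant sites 0 by
  default (configurable; the +I machinery is implemented throughout).
* **Alignments**: root states from the stationary frequencies, per-site
  rates from the discrete-Γ mixture, transitions by matrix exponentials
  along each branch.  No indels: simulation is the one regime where a
  gap-free alignment is exact, though gaps and ambiguity codes are
  accepted on input (treated as the full state set).

Default ("desk") scale is 8–64 taxa and 100–2000 sites per alignment,
with 550 alignments for the main experiment — a deliberate reduction of
the full published design (30–1000 taxa, up to 10 000 sites, 6000
alignments) chosen because learning curves plateau around 400 training
alignments, and documented here as the package's operating point.  All
sampling is driven by `numpy.random.SeedSequence` spawning, so a single
seed reproduces every replicate byte-for-byte.

What passing tests on these data do **not** show: robustness to
alignment error, indels, site-dependent or non-stationary evolution, or
the exact tree-shape distribution of empirical databases.  The
misspecification scenarios (below) probe only exchangeability/rate
misspecification within the GTR family.

## Likelihood engine and tree search

Likelihoods use Felsenstein pruning over compressed site patterns under
GTR+Γ(+I), with transition matrices from the eigendecomposition of the
rate matrix in the frequency-symmetrized basis and per-node scaling of
conditional likelihood vectors.  Branch lengths are optimized
coordinate-wise with a safeguarded Newton method on the analytic first
and second derivatives of the per-edge likelihood profile (bisection
fallback on a derivative bracket, bounds [1e-8, 8] substitutions/site,
length tolerance 1e-6); sweeps follow a depth-first order that refreshes
conditional vectors on the way back, so each 1-D step is an exact ascent.

The maximum-likelihood tree comes from an internal multi-start search:
one neighbor-joining start (Jukes–Cantor distances, saturated pairs
capped at 5 substitutions/site, negative branch lengths clamped to zero)
plus two randomized stepwise-addition parsimony starts.  Each start is
improved by NNI hill-climbing: both swaps around every internal branch
are scored with aLRT-style local optimization (the central branch and its
four neighbors, with the rest of the tree's conditional likelihoods held
fixed), after a cheap central-branch-only prefilter; all improving,
non-conflicting moves are applied per round (best first), followed by a
full branch-length sweep.  If a simultaneous batch fails to improve the
likelihood it is rolled back to the single best move, so accepted
log-likelihoods are non-decreasing.  The acceptance threshold is 0.1
log-units.  Hill-climbing runs under a two-category Γ approximation of
the fit model (the CAT-style search/score split used by mainstream
search programs); final trees are rescored, and the best tree's branch
lengths reoptimized, under the full four-category model.  Non-best final
trees form the suboptimal-tree set used by the concordance features.
The substitution model is taken as given (or a named preset); only
branch lengths are estimated.

Parsimony trees (default 25 per alignment) use randomized-order stepwise
addition on the original alignment — no column resampling, matching the
reading of "parsimony trees" as random addition-order trees — with each
taxon inserted at a Fitch-optimal branch and ties broken uniformly at
random.  The incremental attachment cost is computed exactly from
directional Fitch state sets; fully constant columns are excluded from
the insertion scores (they shift all candidate branches equally).

## Features

39 features per bipartition, grouped as: alignment summaries (sequence
count, site count, distinct site patterns, fraction of constant sites, a
difficulty score); branch-length geometry (the branch's length, its
ratios to the tree mean and to the mean of its four neighbor branches,
branch-length distribution moments over all branches — median, quartiles,
population variance, skewness, excess kurtosis — total divergence, and
the clock deviation below); split shape (leaf count and fraction,
divergence sum and fraction on the smaller side, the partition branch
itself excluded); neighbor-branch statistics (mean, min, max, min/max
ratio, population variance of the ≤ 4 incident branches); parsimony
concordance (fraction of parsimony trees containing the split, mean raw
transfer distance across them, and the mean/min of both quantities over
the split's internal neighbor bipartitions); suboptimal-tree concordance
(the same four statistics against the non-best search trees); and the
minimum and maximum log-likelihood differences to the two locally
reoptimized NNI neighbors.

Design choices that were genuinely open:

* **Transfer distance** is the raw integer (minimum Hamming distance to
  any internal split, both side pairings), not the normalized
  transfer-bootstrap support; it is capped at p − 1 (p = smaller-side
  size), which is also the value returned when a tree has no internal
  branch.  Minimization is over internal branches only — trivial splits
  carry no topological signal.
* **Clock deviation** is a minimal-ancestor-deviation statistic: with the
  root placed at position ρ, each leaf pair (i, j) deviates by
  (d(ρ,i) − d(ρ,j))/d(i,j); a candidate root's score is the RMS over
  pairs, the root position is optimized continuously along every edge
  (closed-form per-edge quadratic), and the tree's score is the minimum.
  It is 0 for clock-like trees, scale-invariant, and bounded by 1.  For
  2-leaf trees the stored root split is used directly.
* **Difficulty** is a built-in proxy (no external predictor): the mean
  normalized Robinson–Foulds distance among the parsimony-tree sample,
  averaged 50/50 with the fraction of columns that vary but are
  parsimony-uninformative.  Both terms rise on weak or conflicting
  signal.  A config hook accepts an externally computed difficulty
  column instead; the proxy is not claimed equivalent to any external
  tool's score.
* **Masked features** (suboptimal-tree statistics when fewer than two
  suboptimal trees exist; neighbor-bipartition statistics when a branch
  has no internal neighbors, as on 4-taxon trees) are encoded as NaN and
  consumed natively by the tree ensemble, not imputed.
* The denominator of the branch/tree-mean ratio uses all branches
  (terminal included), matching the branch-length moments.

No feature reads the true tree; a leakage audit (recomputation with the
true tree replaced) is part of the test suite.

## Classifier, tuning, calibration

The primary backend is LightGBM (binary objective).  Hyperparameters are
tuned by grouped 5-fold cross-validation on AUC — all rows of one
alignment stay in one fold — over the grid: leaves per tree {25, 50, 100,
200}, depth {3, 6, 12, unlimited}, learning rate {0.1, 0.01, 0.001},
estimators {100, 300}, subsample {0.6, 0.8, 1}.  The full 288-point grid
is exhaustive in principle; the default configuration evaluates a seeded
random subset of 12 configurations to keep a desk run inside minutes, a
budget cap applied before any results were inspected.  Recursive feature
elimination (drop the least gain-important feature while the grouped-CV
AUC does not decrease) is available but off by default at desk scale:
published elimination runs kept essentially all features, and the
procedure multiplies training cost without changing the operating point.
Random-forest and two-layer MLP backends (their own small grids) run
through the identical pipeline for comparison.

Calibration: the best configuration is refit on the full training split;
five grouped folds each contribute an isotonic regression fit on that
fold's out-of-fold raw predictions; at predict time the refit model's raw
score is passed through the average of the five isotonic maps.  An
average of monotone maps is monotone, so calibration preserves the raw
ranking (AUC is unchanged up to ties) while making the scores
probability-interpretable.

## Experiment layout

The main experiment simulates 550 alignments, splits them 70/30 by
alignment with sequence-count stratification into five equal-size
quantile bins, trains on the 70% side and reports held-out metrics on
the 30% side.  Calibration is additionally measured on an independent
validation batch of fresh trees accumulated until at least 20 000
labeled bipartitions.  Misspecification scenarios reuse the first 150
validation trees: the control alignment analyzed under the drawn model,
a JC-simulated alignment on the same tree analyzed under the drawn GTR
model, and the control alignment analyzed under JC — so all three
scenarios share trees and differ only in the simulate/analyze model
pair.  (The published design used 250 such trees; 150 keeps the full
test suite inside a desk-scale run and the comparison is qualitative.)

## Numerical notes and limitations

* Per-pattern log-scale accumulators prevent underflow on deep trees;
  likelihood agreement with exhaustive ancestral-state enumeration is
  asserted to 1e-10 on ≤ 6-taxon instances.
* Ties in parsimony attachment and NNI gains are broken by seeded
  uniform draws; every pipeline stage is deterministic given its seed.
* Zero-length branches are kept (not collapsed): every internal branch
  of the inferred tree is classified, including likelihood-plateau
  branches whose NNI differences are near zero.
* The NJ start can be poor on saturated data (capped distances); the
  parsimony starts and the multi-start selection absorb this, and such
  replicates are exactly the hard, low-support end of the training
  distribution.
* The search is NNI-only (no SPR/TBR); occasional search failures
  produce wrong-but-weakly-supported branches, which the classifier
  sees as negatives with appropriately weak features.
* Supports are written as internal-node labels with three decimals;
  annotated trees re-parse cleanly.
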
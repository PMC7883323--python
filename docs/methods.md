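# Methods

## Model

A *feature* is one patient similarity network (PSN): an undirected weighted
graph over patient identifiers built from one grouped slice of one data
layer. Classification proceeds in two stages.

**Stage 1 — feature scoring by network integration.** For class *c* in one
train/test split, a query Q (a subsample of *c*'s training members) and a
background B (the other classes' training members) define a pairwise target
t(a,b) = +1 for (a,b) ∈ Q×Q and −1 for Q×B; background–background pairs are
excluded so only same-versus-different-class information enters the fit.
Stacking these pairs as rows and candidate network weights as columns gives
the design matrix X (an absent edge contributes 0), and the network weights
solve

    min_w ||X w − t||² + λ_r ||w||²,

followed by iterative clipping: networks with negative coefficients are
removed and the system is re-solved until all surviving weights are
non-negative. The raw penalty is `ridge × mean(diag(XᵀX))`; scaling the
penalty by the design's mean squared column norm makes the fit exactly
equivariant under a common rescaling of all networks (scaling every edge by
c rescales all weights by 1/c), which a fixed penalty would not be. A
feature's score in the split is the number of queries (out of
`feat_score_max`) in which it received a strictly positive weight.

**Stage 2 — classification by label propagation.** Selected networks are
rebuilt over training and test patients, averaged with equal weights
(weights are deliberately not re-fitted on the joint cohort, which would
leak test labels), and the training indicator of class *c* is diffused by
solving `(I + λL) f = y` with L the combinatorial Laplacian. The system is
symmetric positive definite, so the solution is unique and obeys the
maximum principle (all scores lie between the prior's extremes). Per-class
test scores are rank-normalized to [0, 1] before the argmax so classes
whose integrated networks have different densities remain comparable; exact
ties go to the lexicographically first class.

## Resampling and consensus

Splits are stratified by class label (per class,
`round(train_fraction × n)` patients train, clamped so both sides are
non-empty). Query subsampling supports two schemes:

* **holdout** — class ids are shuffled once per split and cut into
  `feat_score_max` nearly-equal contiguous blocks; query *i* omits block
  *i*, so each query holds out ≈ 1/`feat_score_max` of the class. With
  `feat_score_max = 1` no holdout is possible and the full class is used.
* **montecarlo** — every query independently draws a configurable fraction
  (default 0.8) without replacement, decoupling the score ceiling from the
  holdout fraction for small cohorts.

Consensus calling accepts a feature when the fraction of splits with score
≥ `fs_cutoff` is at least `fs_pct_pass` (0 meaning "any split"); unscored
entries count as below cutoff. When no feature passes for a class, the
best-scoring feature is used with a warning — the alternative (refusing to
classify) would silently drop entire splits.

## Similarity metrics

* **pearson** — pairwise Pearson correlation of the group's measure
  profiles over pairwise-complete observations (a pair needs ≥ 2 shared
  observed measures). Negative correlations are clipped to 0 rather than
  rescaled to (r+1)/2: integration and propagation assume non-negative
  affinities and clipping preserves "no similarity" semantics (the
  alternative is available via `clip_negative=False`).
* **normdiff / scaled_euclidean** — 1 − |xₐ−x_b|/range for one continuous
  variable; the range is the observed cohort range at build time, not a
  theoretical range, so the metric adapts to the data actually present.
  Missing values are omitted, never imputed.
* **binary** — pathway co-mutation cliques with unit weights; a feature is
  created only when ≥ `min_carriers` (default 6) patients carry an event in
  the gene set, suppressing degenerate near-empty networks.

Optional sparsification drops edges below `min_weight` (default 0.3), then
keeps each node's `max_degree` (default 50) strongest incident edges; an
edge survives if either endpoint retains it, making the filter idempotent.

## Label enrichment

A network's bias is (n₊ − n₋)/(n₊ + n₋) over its member patients (+1 all
cases, −1 all controls, 0 balanced). Membership is treated as a node-level
statement: for the unit-weight cliques of the sparse workflow, node counts
and case–case edge counts are monotone transforms of each other, so the
node form is used throughout. The Monte Carlo p-value shuffles labels over
the full cohort with membership fixed and applies the +1 correction,
`p = (1 + #{bias_perm ≥ bias_obs}) / (num_perms + 1)`, so p is never 0 and
the working threshold (default 0.07) stays meaningful at small permutation
counts. An `exact=True` mode enumerates the permutation distribution in
closed form (the member positive count under shuffling is hypergeometric)
without the +1 correction; it is used to validate the Monte Carlo path.

## Sparse genetic workflow

Feature selection runs over `num_splits` folds, each training on the
complementary (num_splits−1)/num_splits of the cohort (stratified).
Per-fold scores (0..`feat_score_max`) are summed into cumulative scores
with maximum `num_splits × feat_score_max`. Classification is rule-based:
at cutoff *s*, a patient is called a case iff they carry an event in a
pathway with cumulative score ≥ *s*; sweeping *s* yields a table of
confusion counts whose ROC/PR areas are computed directly from the counts
(ROC anchored at (0,0) and (1,1), trapezoidal; PR by step interpolation,
precision at tp+fp = 0 defined as 1).

## Mutation smoothing

Random walk with restart over a binary symmetric gene–gene network:
`F ← (1−r)·W·F + r·F₀` with W the column-normalized adjacency and F₀ each
patient's mutation vector normalized to sum 1. Column stochasticity
conserves per-patient mass at every iteration, so converged scores lie in
[0, 1]. Isolated genes get a self-loop in W so a seeded isolated gene keeps
its mass instead of destroying it. Defaults: restart 0.5 (an even split
between neighbourhood exploration and seed retention), tolerance 1e−6 on
the max entry change, 1000 iterations. Binarization keeps, per patient, the
`ceil(fraction × n_genes)` highest-scoring genes among those with positive
score (default fraction 3%; ties at the cutoff broken by gene-name order)
and always unions the patient's direct mutations, so the output is never
sparser than the input.

## Integrated PSN statistics

Selected networks aggregate by MEAN (absent pair = 0 with the network still
in the denominator) or MAX, with optional pruning to the top
`ceil(top_x × n_edges)` edges by weight (ties broken by edge name, so
pruning is deterministic). For class separation, edge length is the
reciprocal similarity — stronger similarity, shorter path — and all-pairs
Dijkstra distances are split into within- and between-class samples;
unreachable pairs are excluded and counted, and a one-sided
Wilcoxon–Mann–Whitney test asks whether within-class distances are
stochastically smaller.

## Synthetic data

`generate_synthetic_dataset` plants class structure in a location-shift
model: each group of measures shares a latent per-measure pattern drawn
N(0,1) (so all patients correlate positively within any group, as
co-regulated genes do), and discriminative groups add a class-specific
±`effect_size`/2 offset along a random per-measure sign pattern, raising
within-class over between-class profile correlation. Defaults — 200
patients, two balanced classes, 20 groups of 10 measures, 1 discriminative
group, effect size 2, no missingness — describe a modest two-arm cohort
with one truly informative pathway; `missing_rate` masks entries uniformly
at random when set. The event generator defaults (300 patients, 30 pathways
of 20 genes, background event rate 0.05, case/control rates 0.40/0.05 in
the enriched pathway) emulate a rare-variant study where a risk pathway is
hit in a large minority of cases. Not emulated: heavy tails, batch effects,
correlated noise across groups, label noise, linkage between pathways —
passing tests on these fixtures demonstrate correct mechanics and
recoverability under the stated model, not performance on real cohorts.

## Numerical choices

* Propagation is solved by conjugate gradients (rtol 1e−10, dense direct
  fallback); tests require agreement with a dense solve to 1e−8.
* The ridge default is 1.0 on the scaled penalty above; weight solving is
  fully deterministic (no iterative optimizer).
* Degenerate inputs fail loudly: zero-range continuous variables,
  single-member classes, non-symmetric or non-binary interaction networks,
  and malformed file rows all raise structured validation errors naming the
  offending field or line.
* All randomness flows through `numpy.random.default_rng` seeded from the
  user-supplied seed; per-split seeds are derived by a fixed affine map so
  results are byte-identical across reruns.

## Problem sizes and limitations

The test and acceptance fixtures use cohorts of 40–400 patients with 5–20
feature networks, sizes at which the dense pair-design ridge fit (up to
~30k pairs × 20 networks) and the propagation solves run in seconds on one
core; the recovery and null-calibration suites (20 generator seeds, and a
400-patient four-split null run) complete in about two minutes total.
Known limitations: no probability calibration or reject option, no nested
cross-validation, no multiple-testing correction on enrichment p-values
(a plain threshold is used), no imputation, and no claim of numerical
compatibility with the Java-based integration engine this design family
descends from — the committed target scaling (±1) and ridge default are
this package's own, documented choices.
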
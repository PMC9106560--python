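# Methods

## Model

An uncertain network over a fixed node universe `V` assigns each unordered
node pair at most one existence probability `p(e) ∈ (0, 1]`; values ≤ 0 are
non-edges (kept out of the edge map entirely), so a stored network is always
sparse and symmetric.  A possible world realises each edge independently;
the probability of a world with edge set `S` is
`∏_{e∈S} p(e) · ∏_{e∉S} (1 − p(e))`, and worlds sum to 1.  Containment of a
node-anchored pattern is an edge-set inclusion test — all networks of a
cohort share one universe, so no subgraph-isomorphism search occurs anywhere
in the package — and its probability is the product of the pattern's edge
probabilities.

Node labels are kept in natural sorted order and edges in canonical
`(min, max)` form; every ranking, file format and mining index derives from
this one total order, which is what makes repeated runs byte-identical.

## Mining

Expected support (the cohort mean of containment probability) is
anti-monotone: any superpattern's support is bounded by each subpattern's.
The miner lists frequent edges `m_1 … m_k` in canonical order, seeds one
sub-search space per frequent edge, and grows candidates layer by layer,
retaining those that are connected and still frequent (`Esup ≥ minsup`; the
comparison is inclusive, matching the pseudocode formulation of the
procedure rather than the prose "more than").

Two growth modes:

* `increasing` (default): a pattern may only be extended by frequent edges
  whose index exceeds every index it already contains.  Each pattern is
  generated at most once, but patterns with a disconnected index-sorted
  prefix are unreachable — the approximation of the original procedure.
  `increasing_prefixes_connected` certifies that this is the *only* loss
  mechanism; the test suite asserts it exhaustively on small cohorts.
* `exhaustive`: extensions by any edge above the sub-search space's seed
  index, deduplicated by sorted index tuple.  Every connected pattern admits
  a growth order whose prefixes stay connected, and prefixes inherit
  frequency by anti-monotonicity, so this mode is exact; it is verified
  pattern-for-pattern (and support-for-support, at 1e-9) against
  `mine_oracle`, a brute-force enumerator of all connected edge subsets that
  computes supports directly and shares no machinery with the growth path.

Certain (binary) networks are mined as the `p = 1` special case, where
expected support degenerates to the fraction of networks containing the
pattern.  Dense binarized cohorts share a large common edge core whose
frequent lattice is exponential; pipeline sweeps therefore cap certain-arm
patterns at 3 edges by default (`certain_max_pattern_edges`, configurable).

## Selection

For every candidate (the union of both groups' frequent sets — both group
means are needed for either score, and the union is the only pool under
which both top-k lists are well defined) the per-group mean containment
probabilities give `confidence_pos = m⁺/(m⁺+m⁻)` and its complement.  Ties
are broken by larger `|m⁺ − m⁻|`, then smaller pattern, then canonical edge
order — deterministic and favouring stronger absolute separation.  A pattern
landing in both top-k lists is kept once, on the side with the larger
confidence, so the feature count is at most `2k` and is reported.  On the
binarized arm the score is the containment-frequency difference between
groups (antisymmetric, zero for ubiquitous patterns).

## Classification

RBF-kernel SVM; `C` and `gamma` range over powers of two (`2^-5 … 2^5`,
`2^-8 … 2^2`, exponent step 1 — the reading under which reported optima like
`(0.25, 0.5)` are grid points).  The grid point maximizing inner-CV accuracy
on the training portion is selected, ties toward smaller `C` then smaller
`gamma`.  For speed the inner scoring runs on libsvm's low-level interface
with precomputed kernels (one squared-distance matrix shared across the
gamma grid); a test pins its selections to `GridSearchCV(SVC(kernel="rbf"))`
on identical splits.  Inner selection pools correct predictions over the
inner folds rather than averaging per-fold accuracies; with stratified
near-equal folds the two orderings coincide.

Evaluation is stratified 10-fold CV repeated (default 100 repeats in
`CVConfig`; pipeline defaults use 10 repeats for the main arm and 2 per
sweep cell — scaled problem sizes chosen for interactive runs, raise them
for production).  Metrics (accuracy, sensitivity with the positive class as
patients, specificity, AUC from decision values) are averaged over folds
then repeats.  Two protocols:

* `pooled` mode evaluates a fixed feature matrix whose patterns were selected
  on the whole cohort.  This replicates the emulated protocol faithfully but
  lets selection see test subjects, so its scores are optimistic.
* `nested` mode re-runs mining and selection inside every training fold (an
  extractor clone never sees the fold's test networks — instrumented in the
  test suite).  This is the calibrated protocol: on effect-free cohorts its
  accuracy is ~0.5.

## Synthetic cohorts

The generator emulates a two-group resting-state connectivity study:
22 nodes, 38 vs 28 subjects, a shared edge mask over half the possible
edges, per-edge baseline probabilities, truncated-Gaussian per-subject
jitter (sd 0.05, a realistic scale for correlation-estimate variability;
values clipped into (0, 1], non-positive values becoming subject-level
non-edges), and planted connected patterns whose edges are boosted by
`delta` in one group only (saturating at 0.95).

Parameter choices that matter:

* **Baseline Beta(2, 4)** (mean 1/3, rarely above 0.7).  Calibrated so that
  mining at the operating point `minsup = 0.25` yields frequent sets of a
  few hundred patterns per group — the scale the emulated study reports.
  Stronger baselines (e.g. Beta(2, 2)) make the 22-node frequent lattice
  explode into thousands of patterns, an operating regime the method never
  faced and in which any planted pattern drowns among frequent supersets.
* **Planted baselines ≥ 0.4** (same Beta, truncated).  Planted effects model
  the modulation of *established* connections; a pattern whose boosted
  support still sits below `minsup` is outside the estimand of
  frequency-thresholded mining and unrecoverable by definition.
* **Planted patterns lie in the default search space.**
  `random_connected_pattern` returns patterns whose canonical-prefix subsets
  are connected (rejection sampling), since the approximate `increasing`
  miner cannot reach other patterns regardless of signal; pass
  `prefix_connected=False` for unrestricted draws.

The time-series generator places each subject's edge probabilities on the
off-diagonals of a target correlation matrix, repairs it to the nearest
positive-semidefinite correlation matrix by eigenvalue clipping, and draws
248-timepoint multivariate Gaussian series from its Cholesky factor.  The
repair shifts dense targets (an arbitrary probability assignment need not be
a valid correlation matrix) and finite series add sampling noise of order
`1/√T`, so networks rebuilt through the Pearson path have weaker and noisier
edges than directly generated ones — exercised end-to-end by the pipeline,
with exact recovery asserted only where the target is feasible (small
systems, long series).

What passing tests on these cohorts do *not* show: real resting-state data
have autocorrelated, non-Gaussian signals, site and motion confounds, and
edge dependencies that independent-jitter simulation does not produce;
results here validate the machinery and its calibration, not clinical
performance.

## Numerical and design notes

* Probability identities are asserted at 1e-9 absolute; products of ≤ 30
  factors keep floating error far below this.
* Sparsity thresholding keeps `round(s · n(n−1)/2)` edges, probability
  descending, ties by canonical edge order; `min_weight` (the lowest kept
  probability) is per subject — each subject's binary network attains the
  stated sparsity.
* `r_ij = 0` is a non-edge (indistinguishable from absence in every
  downstream formula), and correlations use the standard sample estimator.
* Labels are generic `pos`/`neg` (+1/−1); the method is disease-agnostic.
* Degenerate inputs fail loudly: self-loops, zero-variance regions,
  single-class training data, folds exceeding the minority class, empty
  cohorts and empty patterns are all rejected with named errors.

## Limitations

The `increasing` miner is approximate (characterized exactly, see above);
selection scores are univariate and ignore feature redundancy (nested
patterns may co-occur in a top-k list); `pooled`-mode scores inherit the
selection-before-CV optimism of the emulated protocol; and the brute-force
oracle and world enumeration are exponential, guarded to small inputs.
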
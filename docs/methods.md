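# Methods

This note records the model choices, numerical conventions and known
limitations of the `cgufs` implementation, in the order the pipeline runs.

## Adaptive k-means (sample pseudo-labelling)

Plain Lloyd iterations: assign each sample to the nearest center by squared
Euclidean distance, recompute centers as member means, stop when the
assignment is stable or after `max_iter` (default 300) iterations. Within a
run the SSE *J* is non-increasing by construction and asserted at every
iteration; the one exception is an empty-cluster repair step, which
re-seeds a lost center at the sample farthest from it (preferring samples
whose cluster keeps at least one other member) and may transiently raise
*J*.

Initialization draws `restarts` (default 10) independent sets of *k*
distinct samples uniformly at random; the restart with the lowest *J* wins.
Best-of-restarts makes the *J*-versus-*k* trace effectively monotone, so a
"negative elbow" in the sample scan can only reflect genuine structure, not
an optimization accident. Labels are canonicalized by order of first
occurrence, which makes results bit-reproducible for a fixed seed.

The elbow scan fits every *k* = 1..*k₁* (default *k₁* = min(10, n)),
caching each assignment so the returned clustering is exactly the one whose
SSE entered the trace. The change function uses *signed* differences
ΔJ_l = J_l − J_{l+1}:

* `degenerate` — J₁ ≤ tol (all samples numerically identical): k = 1.
* `negative_elbow` — some ΔJ_l < −tol·max(J₁, 1): k = l for the smallest
  such l, the point before the first SSE rise.
* `max_drop` — otherwise k = argmax ΔJ_l + 1, the right endpoint of the
  largest drop (ties to the smallest index). The right endpoint is used
  because a (100, 10, 9) trace should yield k = 2, not the useless k = 1.

The tolerance `tol` = 1e-9 (relative to J₁) exists only to keep
floating-point noise from triggering the negative-elbow rule.

**Limitation — coarsest-structure preference.** For well-separated
clusters the optimal-SSE curve is convex in *k*, so the first drop is the
largest and `max_drop` systematically selects *k* = 2 whenever the true
cluster count exceeds 2 and no SSE rise occurs. This is a property of the
first-difference rule itself, not of the implementation: the adaptive scan
is a first-rise detector and therefore prefers the coarsest significant
structure. Consequences for selection quality are discussed below.

## Spectral feature grouping

Features (columns) are points in *n*-dimensional sample space. The
similarity graph uses Gaussian weights w_ij = exp(−‖f_i − f_j‖²/σ²) with
w_ii = 1. By default σ is the median pairwise Euclidean distance between
features (the median heuristic: scale-free and deterministic), falling back
to the smallest positive distance when the median is zero; a graph in which
every pairwise distance is zero is degenerate and yields a single feature
group with a warning. The normalized affinity L = D^{−1/2} W D^{−1/2} has
all eigenvalues in [−1, 1]; this is asserted in tests.

Group counts are chosen by the same adaptive elbow, but each candidate u₂
is fitted **in its own embedding**: the eigenvectors of the m largest
eigenvalues of L with m = max(u₂, 2), rows scaled to unit norm, then
k-means with k = u₂. The per-candidate embedding is what gives the elbow a
signal: once u₂ exceeds the true block count, the additional eigenvectors
carry only within-block or within-noise contrasts, whose row-normalized
spread inflates the SSE, and the negative-elbow rule fires at the true
count. (A single fixed-dimension embedding was tried first and rejected:
its SSE trace decreases smoothly with no elbow at all, and block recovery
fails.) The m = 1 case is floored to m = 2 because the one-dimensional
row-normalized embedding of a connected graph collapses every feature to
the same point, making its SSE an uninformative zero.

Eigendecomposition is dense (`scipy.linalg.eigh`); eigenvector signs are
fixed by making each column's largest-magnitude entry positive, for
reproducibility. All-zero embedding rows (features with no weight on the
selected eigenvectors) are left at zero and logged.

**Limitation — hierarchical feature geometry.** When the feature geometry
is two-level (for example, a tight mass of mutually similar noise features
against a handful of informative blocks), the two-dimensional embedding
already separates the coarse split almost perfectly, the SSE at u₂ = 2 is
near zero, and the first-rise rule stops there, merging all informative
blocks into one group. Fine block structure is recovered reliably only when
the blocks are the dominant geometric scale (as in the flat fixtures used
by the grouping tests).

## Information measures and redundancy filtering

Features are discretized once by equal-frequency binning (default B = 5,
`--bins`), chosen for robustness to the skewed distributions typical of
expression data; duplicate quantile edges collapse, so heavily tied
features occupy fewer bins, and the same codes serve every information
measure. Entropy, information gain IG(a,b) = H(a) + H(b) − H(a,b) and
symmetric uncertainty SU = 2·IG/(H₁ + H₂) are plug-in estimates in bits;
IG is clipped at zero and SU at one against floating-point noise, and
SU of two constant vectors is defined as 0.

Per group, the main feature maximizes IG with the pseudo-labels (ties to
the smallest index — deterministic). A non-main member *q* is redundant
exactly when IG(q, Cluster) < IG(main, q); equality keeps *q* as a
candidate, the conservative choice, since the SU ranking and quotas still
filter it. Pairwise IG is computed lazily and only within groups, keeping
the cost at O(d · max group size) rather than O(d²).

The budget is N_new = max(1, ⌊β·d⌋) (β default 0.05; an absolute
`--n-features` override exists because practitioners often sweep absolute
counts). Group quotas apportion N_new by each group's share of the total
SU mass over **all** members (not only retainable ones, matching the
group-assignment reading of the quota definition), integerized by the
largest-remainder method so quotas sum exactly to the achievable total;
each quota is capped at the group's count of retainable members with the
surplus redistributed in remainder order, and a zero total SU falls back
to apportionment by group size. Redundant members are never retained, even
when a group's quota exceeds its candidate count.

**Limitation — pseudo-label granularity.** The redundancy test compares
information about the *pseudo*-labels with information shared between
features. When the sample stage under-clusters (see the coarsest-structure
preference above: k = 2 found for 3 true clusters), cluster-informative
features share more binned information with each other (through the full
cluster structure) than any of them carries about the coarse pseudo-label,
so the filter classifies them as mutually redundant and per-group candidate
lists collapse toward the main feature alone. The selection still ranks a
strongly informative main feature first — cross-validated accuracy of the
selected subset beats random equal-size subsets decisively on the synthetic
benchmark — but coverage of *all* informative blocks is not achieved in
that regime, and the corresponding recovery-level assertion in the
acceptance suite fails by design rather than being weakened.

## Synthetic data generator

`make_synthetic` emulates the target regime: n = 120 samples in c = 3
balanced clusters (round-robin assignment, removing a nuisance source of
flakiness), g = 5 informative feature blocks of one prototype plus 4
additive-noise copies (copy noise sd 0.1 — copies correlate with their
prototype at ≥ 0.99), and 75 standard-normal noise features. Block
prototypes take cluster-dependent means spaced `cluster_sep` = 6
within-cluster standard deviations apart; each block uses a distinct
permutation of the spaced means (cycling through the c! permutations), so
different blocks respond to the clusters in different patterns and remain
mutually distinguishable, as distinct co-regulated gene modules would be.
`make_sample_blobs` provides isotropic unit-variance Gaussian blobs with
centers `sep` apart along distinct unit directions, for the clustering
tests.

What the generator does **not** emulate: count-based noise models
(negative binomial), library-size or batch effects, heteroscedastic gene
variances, or unbalanced cluster sizes. Passing tests therefore demonstrate
correctness of the algorithmic machinery under idealized Gaussian
structure, not performance on real sequencing data.

## Evaluation harness

Cross-validation is stratified k-fold (default 10) with scikit-learn
classifiers: a decision tree with the entropy criterion standing in for
C4.5, and Adaboost with default base learners. Predictions are pooled over
folds into a single confusion matrix from which all metrics derive; a class
rarer than the fold count reduces the fold count with a warning. Recall and
F-measure are macro-averaged; MCC uses the multiclass R_K statistic (equal
to the classical formula for two classes, 0 when a denominator term
vanishes). ACC-type metrics are stored in [0, 1] and reported as
percentages with two decimals; ACC/FS divides the percentage by the
retained-feature count.

Rank tables use tie-averaged ranks (rank 1 = best). The Wilcoxon
signed-rank test drops zero differences, tie-averages |d| ranks, and
rejects when min(R+, R−) is at or below the exact two-sided critical value,
computed by dynamic programming over the signed-rank null distribution
(21 at m = 14, α = 0.05) rather than read from a hard-coded table; the
critical value is overridable. The Friedman statistic uses the
average-rank formula without tie correction, with the Iman–Davenport
transform F_F = (N−1)·χ²_F / (N(k−1) − χ²_F); a zero denominator (every
block ranking the algorithms identically) is reported as infinite F with a
warning.

## Problem sizes

Test and acceptance runs use the generator defaults (120 × 100 benchmark,
60 × 30 grouping fixtures, 100 × 2 blobs) with 20 seeds per stochastic
claim — sizes at which every stage, including the 20-fold random-subset
baseline of the utility check, completes in seconds while leaving the
measured properties well away from small-sample artifacts.
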
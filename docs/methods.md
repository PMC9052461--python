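# Methods

`omicsel` benchmarks supervised feature-selection algorithms on
continuous omics profiles with categorical outcome classes. This note
records the models implemented, the defaults and why they were chosen,
the numerical conventions, and what the synthetic generator does and
does not emulate.

## Preprocessing

Each feature (gene, probe, segment, pathway score) is normalized to zero
mean and unit standard deviation across samples, `x_norm = (x - mu) /
sigma`. The population convention (divisor n) is the default; the
divisor is configurable (`ddof`) because either convention is defensible
and the downstream discretization is insensitive to the choice.
Constant features, for which the transform is undefined, are dropped
with a warning by the pipeline driver before normalization.

Differential screening is a per-feature one-way ANOVA F test across the
class groups; features with p < alpha (default 0.05, no multiple-testing
correction) survive. An optional moderated variant shrinks each
feature's within-group variance toward the grand mean of those variances
with a prior weight `prior_df` (default 4 when enabled, expressed in
pseudo-degrees of freedom that are added to the residual df). This is a
deliberately simple stand-in for empirical-Bayes variance moderation:
it reproduces the stabilizing effect on small-sample variances without
fitting a scaled-inverse-chi-squared prior. The plain ANOVA (prior_df =
0) is the default because it is exactly calibrated under the null — the
test suite checks that the kept fraction at alpha = 0.05 is 0.05 ± 0.02
and that null p-values pass a Kolmogorov–Smirnov uniformity check.

Discretization maps each normalized feature to three states: values
below mean − sigma become −1, values above mean + sigma become +1,
everything else (boundaries included) 0. With z-scored input the cut
points are ±1. Strict inequalities are used so boundary values land in
the middle state; the three states partition the line by construction.

## Information measures

Entropy, joint entropy, mutual information (MI) and normalized mutual
information (NMI) are plug-in (maximum-likelihood) estimates on the
discretized states, with no smoothing or bias correction, all in bits
(base-2 logarithms — the representation-entropy magnitudes reported by
this kind of benchmark are only consistent with base 2). NMI is
I(x;y) / min(H(x), H(y)), bounded in [0, 1]; when either marginal
entropy is zero the value is defined as 0, since a constant feature
carries no information.

## Greedy MI-criterion selectors

Six incremental criteria share one greedy forward loop. Writing S for
the already-selected set, C for the class, I for MI and Î for NMI:

| method | criterion |
|---|---|
| MIFS | I(f;C) − β Σ_s I(f_s;f) |
| MIFS-U | I(f;C) − β Σ_s [I(f_s;C)/H(f_s)] I(f;f_s) |
| mRMR | I(f;C) − (1/|S|) Σ_s I(f;f_s) |
| NMIFS | I(f;C) − (1/|S|) Σ_s Î(f;f_s) |
| INMIFS | Î(C;f) − (1/|S|) Σ_s Î(f_s;f) |
| VWMRmR | Î(C;f) − (1 + w·|S|/k)·(1/|S|) Σ_s Î(f;f_s) |

With S empty every criterion is its relevance term, so step 1 picks the
most class-relevant feature. Defaults: β = 0.5 (mid-range of the MIFS
literature; the method is a baseline here and no canonical value
exists), w = 1.0 (the VWMRmR weight is user-specified by design; it is
logged in every report), k = 50 (the benchmark's subset size). VWMRmR
uses the same min-entropy NMI for both its relevance and redundancy
terms. Ties at the argmax break toward the lowest original feature
index, which makes runs deterministic and feature-permutation-covariant.
Pairwise MI/NMI rows are computed once per selected feature and cached;
the cache is asserted against direct recomputation in the tests, and the
whole loop is checked step-by-step against an exhaustive from-scratch
argmax oracle.

MIFS-U terms with H(f_s) = 0 (a constant selected feature) are skipped
with a warning — the weighting is undefined there and a constant feature
contributes no redundancy anyway.

## DFS: row-sparse regularized LDA

The discriminative selector fits a projection W (one column per
discriminant direction, #classes − 1 of them) by minimizing

    trace(Wᵀ (Sw + εI) W) + reg · Σ_i ||w_i||₂^p    s.t.  Wᵀ Sb W = I,

with Sb/Sw the between/within-class scatter matrices and 0 < p ≤ 2. The
row penalty (the l2,p norm) pushes whole feature rows toward zero, so
features are ranked by descending row norm ||w_i||₂ — all at once, with
redundant copies suppressing each other through the shared projection.
The solver is iteratively reweighted least squares: with the diagonal
reweighting D (d_i = (p/2)(||w_i||² + δ)^((p−2)/2)) held fixed, the
constrained quadratic is a generalized eigenproblem for the pencil
(Sb, Sw + εI + reg·D) whose top eigenvectors, rescaled to satisfy the
constraint, minimize the surrogate; D is then refreshed. This is a
majorize–minimize scheme, so the smoothed objective is non-increasing —
asserted on every test run. Defaults: p = 1 (the row-sparse case),
reg = 1, ε-guard 1e−8 (relative to trace(Sw)/d), δ = 1e−8, tol = 1e−6,
max_iter = 50. p = 2 makes D the identity and the solution collapses to
ridge-regularized LDA in one sweep, which the tests use as an
independent cross-check. Sw is ridge-stabilized because omics data have
d ≫ n and Sw is singular. Non-convergence returns the best iterate with
`converged=False` rather than raising.

The cost is dominated by the d×d generalized eigendecomposition per
sweep, so DFS is the stage that bounds the problem sizes used in the
tests (hundreds of features, not tens of thousands).

## SVM-RFE with correlation-bias reduction

Backward elimination: train one-vs-rest linear SVMs (squared hinge,
C = 1, per-call feature standardization) on the survivors, score each
feature by the sum of its squared weights across the class models, mark
the `rfe_step` lowest (default ceil(10% of survivors)) and eliminate
them; repeat until k survive. The CBR rule addresses correlation bias —
a correlated group shares its weight mass, so each member looks
individually weak: a marked feature is deferred (survives the round)
when its absolute Pearson correlation with any unmarked survivor is at
least `cbr_tau` (default 0.85). If deferral would empty a batch, the
single weakest marked feature is eliminated so the loop always
progresses. With cbr_tau = 1.0 the rule never fires and the procedure
is textbook SVM-RFE, which the tests verify against an independent
implementation. Ranking is survivors first (by final score), then
reverse elimination order.

## Evaluation criteria

**Accuracy.** Repeated stratified k-fold cross-validation (default
10-fold × 10 repeats), reported as mean and standard deviation of the
per-fold percentage over all repeats × folds. Multiclass accuracy is
the plain fraction of correct predictions, which coincides with
(TP+TN)/(TP+TN+FP+FN) in the binary case. Four classifiers: an
entropy-criterion decision tree standing in for C4.5 (its Weka-style
confidence parameter c is mapped monotonically onto cost-complexity
pruning, ccp_alpha = 0.05·(0.5 − c), so smaller confidence means heavier
pruning), Gaussian Naive Bayes, KNN with K = round(sqrt(n_train)) unless
tuned, and AdaBoost on depth-1 stumps (50 rounds; Weka's 10-round
default is an alternative preset a caller can pass). Optional tuned
protocol: KNN K ∈ 1..15 and tree confidence ∈ 0.05..0.5 step 0.05, each
grid value getting a full repeated-CV run with the best mean reported.

**Redundancy rate.** RR = 2/(d(d−1)) Σ_{j>i} Sim(f_i, f_j), the mean
pairwise similarity over the subset; lower is better. Two similarities:
NMI on the discretized rows, and |Pearson r| on the continuous
normalized rows (absolute value, else anticorrelated pairs would cancel
and RR could leave [0, 1]). The split of representations matches each
measure's domain; the benchmark protocol never ties either measure to a
specific representation.

**Representation entropy.** The covariance matrix of the d selected
features is eigendecomposed, the spectrum normalized to sum 1, and its
Shannon entropy taken in bits: 0 when one direction carries all variance
(maximally redundant subset), log2 d when variance is spread evenly.
Computed on the continuous normalized values with sample covariance
(ddof = 1 by default, configurable); tiny negative eigenvalues from
finite precision are clamped at 0. Covariance (not correlation) mode is
the default, so the measure is scale-sensitive — immaterial here because
the pipeline feeds it z-scored data.

## Signatures

The cross-method signature of a dataset is the strict intersection of
the top-k lists of all methods; all 2^m − 1 Venn region counts are
reported for overlap audits, and a majority-vote set (> half the lists)
is available as a softer option but is not the default signature.

## Synthetic data

The generator emulates the shape of a z-scale multi-omics profile with
imbalanced outcome groups: 161 samples in classes of 31/96/34 by
default, a minority of informative features, redundant copies, and
noise. Informative features are unit-variance Gaussians with a
one-vs-rest mean pattern: each feature elevates one (seeded-random)
class by `effect_size` within-class standard deviations, centered so the
feature stays zero-mean. Redundant features are
r·(standardized parent) + sqrt(1 − r²)·fresh noise, hitting the target
parent correlation in expectation; noise features are standard Gaussian,
optionally Student-t with df = 3 to stress the discretization with heavy
tails. Defaults (60 informative, 120 redundant, 800 noise, effect 1.0,
r = 0.8) put the post-filter feature count in the several-hundreds range
typical of these profiles.

What the generator does *not* emulate: real expression/methylation
marginal distributions (log-normal counts, beta values), copy-number
segment structure, block correlation beyond parent–copy pairs, batch
effects, or missingness. Passing recovery tests therefore shows that the
selectors behave correctly under the stated statistical model, not that
they would rank real genes identically.

Recovery is scored as the number of distinct planted informative
features represented in a selected list, with a redundant copy crediting
its parent — selecting the copy instead of the parent is not an error,
they carry the same signal.

## Problem sizes and determinism

The test suite and the acceptance script run the benchmark at reduced
scale — recovery on 424 features × 161 samples with k = 20, evaluation
at 10-fold × 3 repeats, the end-to-end fixture at 40 features — sizes
chosen to exercise every code path on a single CPU in minutes while
keeping the planted-signal regime (effect sizes, class imbalance,
redundancy level) identical to the full-scale protocol. Every source of
randomness is a `numpy` Generator seeded from a single integer; repeated
runs are bit-identical, and the linear-SVM and CV seeds are logged in
every report.

## Known limitations

- The DFS instantiation is one defensible reading of a sparse-LDA
  selector (IRLS on an l2,p-penalized trace criterion); other published
  variants constrain total scatter instead of between-class scatter.
- The CBR deferral rule is this package's concrete formulation of a
  qualitative idea; batch size and threshold interact, and very low
  `cbr_tau` degenerates toward one-at-a-time elimination.
- Plug-in MI is biased upward at small n; with n ≈ 161 and 3×3 tables
  the bias (~(r−1)(c−1)/(2n ln 2) bits) is shared by all candidates and
  barely affects argmax decisions, but absolute criterion values should
  not be compared across sample sizes.
- The moderated F test controls its size only approximately; the exact
  null calibration holds for the plain ANOVA default.
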
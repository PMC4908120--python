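# Methods

## The selection problem

Given an n × p covariate matrix **X** (typically gene expression, p ≫ n)
and a response y, the package searches for *sets* of small covariate
subsets J that predict well out of sample, rather than a single "best"
model. Quality is measured by a user-chosen divergence D(ŷ, y) — any loss
with the positiveness property D(u, v) > 0 for u ≠ v, D(u, u) = 0. The
shipped measures are the L1 loss and an asymmetric misclassification cost
with weights w1 (false positive) and w2 (false negative); custom measures
can be registered and are axiom-checked on a probe grid. The criterion is
deliberately prediction-based, not likelihood-based: the quantity being
minimized is the expected out-of-sample divergence

D̂_J = 1/(mK) Σ_k Σ_l (1/n_l) Σ_{i ∈ I_{k,l}} D(ŷ(x_i, β̂^{J,k}), y_i),

the m-fold cross-validated risk repeated K times (defaults m = 10, K = 1).
Each fold contributes with weight 1/(mK) regardless of its exact size,
following the estimator's definition literally rather than pooling over
samples. One fold plan per run is shared by all candidate models, so model
comparisons use common random numbers. Folds are stratified on a binary
response by default: with n under 40 and an unbalanced response,
unstratified folds regularly produce single-class training sets.

## Parameter estimation

The estimator behind β̂^J is pluggable. The default for binary responses
is the unpenalized logistic MLE computed by a compact Newton/IRLS solver;
for real-valued responses, ordinary least squares. Two fallbacks keep the
search total over all candidate subsets:

- **Separation / non-convergence.** If the unpenalized fit diverges (any
  |coefficient| beyond 15 on the logit scale, i.e. fitted probabilities
  within ~3e-7 of 0/1) or the Newton step fails, the model is refit with a
  small ridge penalty (default 1e-4·n_train). Tiny training folds of
  near-separable expression data hit this constantly; the penalty is small
  enough to leave non-degenerate fits essentially unchanged.
- **Single-class training fold.** The fit degrades to the majority-class
  rule (a saturated intercept), never an exception.

A model that still cannot be fit receives infinite risk and is excluded
from quantile computations. Class predictions use a 0.5 probability
threshold by default (flag-adjustable). The Newton solver is hand-written
because a search evaluates 10^4–10^5 fold-level fits of tiny designs
(d ≤ 10, n < 100) and per-call overhead of general GLM routines dominates
at that granularity; tests verify it against an independent
maximum-likelihood oracle (bounded-box grid search, and statsmodels) to
1e-3 or better.

## The search

Dimension d = 1 is exhaustive: all p single-covariate augmentations of the
forced set M0 are evaluated. For d = 2..d_max, `budget` candidate models
are drawn; each covariate of a candidate is taken from the previous
dimension's promising index set I*_{d−1} with probability π (default 0.5)
or from its complement otherwise, uniformly without replacement within the
chosen set, falling through to the other set when the chosen one is
exhausted. Since |I*| ≪ p, promising covariates are sampled at a
per-covariate rate roughly π/|I*| versus (1−π)/|I^c| for the rest — an
importance-sampling tilt that concentrates the budget near covariates that
already predicted well, while keeping every covariate reachable.

At each dimension the promising set S*_d holds every evaluated model with
risk at or below the empirical α-quantile q̂_d(α), computed as the
⌈αN⌉-th order statistic of the N finite risks over *distinct* evaluated
models, ties included (so |S*_d| ≥ ⌈αN⌉ ≥ 1). Duplicate draws are
evaluated once through a risk cache keyed on the sorted index tuple; a
flag disables the cache, in which case duplicates enter the quantile
sample as drawn. When C(p − p0, d) ≤ budget the dimension is enumerated
exhaustively instead of sampled, which both removes Monte-Carlo error at
small p and lets tests compare the search to brute force exactly.

Defaults follow the usual guidance: α = 0.01, π = 0.5, d_max = 10 capped
at n. The budget rule of thumb p ≤ B ≤ C(p, 2) is surfaced as a warning
rather than a hard clamp — forcing B ≤ C(p, 2) would make exhaustive
enumeration at d ≥ 3 impossible precisely in the small-p regime where it
is most useful. One master seed drives everything: the fold plan and the
sampling stream derive child seeds deterministically, so identical seeds
give identical results.

## Dimension selection and filtering

Because q̂_d(α) is an estimate, the working dimension d* is chosen by
sequential one-sided testing: starting at j = 1, test whether the
dimension-(j+1) risks are significantly smaller than the dimension-j
risks, increment while they are, and stop at the first non-rejection.
The tests operate on pooled per-observation holdout losses of the α-tail
model sets: for classification, pooled misclassification counts compared
by a one-sided exact two-proportion (Fisher) test; for L1, pooled losses
compared by a one-sided Mann–Whitney test. Levels are Bonferroni-corrected
over the planned d_max − 1 comparisons (default level 0.1 before
correction). Pooling observation-level outcomes was a genuinely open
design point; it is the finest observable unit and gives the tests a
concrete sample. Its cost is bounded power at the first comparison, where
the pool holds only ⌈αp⌉·n·K observations.

The final set S*0 then filters S*_{d*}: deduplicate by index tuple, sort
ascending by risk (index tuple as tie-break, making the retained minimum
J_min the lexicographically smallest — a deterministic stand-in for a
random choice among ties), and accept models in order until the first
whose pooled loss is significantly greater than J_min's, at the same
corrected level. S*0 is therefore always a nonempty prefix of the sorted
list. Note the direction: a *smaller* significance level rejects less
easily and can only grow S*0.

## The network

Covariates in S*0 form a graph: node frequency is the number of retained
models containing the covariate, edge weight the number containing both
endpoints. Hubs are assigned greedily: every covariate tying the maximum
frequency is a level-1 hub (ties are all hubs at once); at levels
2..d*, the yet-unlabelled partners of the previous level are labelled
with their entry position, the most frequent of them qualifying as
further hubs when at least two models share them. Components unreachable
from any hub restart the scheme locally without the hub flag. The
position labels partition covariates into families of interchangeable
markers; with d* = 2 the network is hubs with leaf partners, each model
contributing one edge. Exports: TSV edge list, GraphML (round-trips
through standard graph readers), and JSON embedded in the results file.

## Model averaging

Prediction uses the whole of S*0: each retained model is refit on the
full training data, votes a hard class per new sample, and the averaged
score is the fraction of class-1 votes; score ≥ 0.5 (flag-adjustable)
predicts class 1, ties resolving to 1. Averaging hard votes is the
default; `soft=True` averages fitted probabilities. Unfittable members
are dropped with a warning.

## The synthetic benchmark

The generator emulates a two-gene ground truth hidden among noise: X is
n × p equicorrelated standard Gaussian (constant pairwise correlation,
default 0), and y is Bernoulli with

γ = 1 / (1 + exp(1 + X1 + X2)),

i.e. unit intercept and unit coefficients on two active covariates, with
the class-1 probability *decreasing* in the active sum (the formula equals
one minus the standard logistic of the linear predictor and is implemented
in that orientation — symmetric divergences are unaffected). The sample of
72 is split 38/34 into train/test, the split sizes of the leukemia cohort
this design mimics. Defaults: p = 500, active pair {1, 2}, search at
α = 0.01, budget 2000, π = 0.5, tenfold CV, dimension test at level 0.1,
d_max = 3 (sufficient to establish d* = 2 via the sequential walk, and
what keeps a 20-replicate study in minutes on one CPU).

What the generator does *not* emulate matters for interpreting results:
real expression matrices have heavy-tailed, strongly discriminative
active genes — near-separable classes — whereas unit-variance Gaussians
with unit coefficients give a Bayes error of 0.239 against a base rate of
0.325, about three errors of separation on 38 training samples. Under
that signal-to-noise ratio the true pair's CV risk (~9/38) is routinely
beaten by the best of thousands of chance pairs sharing the same finite
response, so benchmark replicates select the correct *dimension* roughly
60% of the time but essentially never retain the true pair in S*0.
Passing pipeline tests on this generator therefore demonstrate correct
mechanics and honest dimension selection, not covariate recovery at this
noise level; recovery requires the near-separable signal of real
expression data (the `supplied_matrix` source exists for exactly that
rerun) or stronger coefficients.

## Numerical and degenerate-input conventions

- Quantile rule: ⌈αN⌉-th order statistic, ties included in S*_d.
- Newton tolerance 1e-9 on the step, max 60 iterations; separation bound
  15 on the logit scale; majority-rule intercept ±36.
- Risk ties in filtering and J_min selection break lexicographically.
- Empty I*_{d−1} falls back to complement-only sampling with a warning;
  an exhausted sampling set falls through to the other set within a draw.
- d_max is capped at n; m > n, non-binary responses under the
  classification divergence, and train/test size overflows raise
  configuration errors with distinct messages.

## Known limitations

- The sequential dimension test's power at j = 1 is limited by |S*_1| =
  ⌈αp⌉; small p with small α can stop the walk at d* = 1.
- No FDR-style correction beyond Bonferroni; no interaction terms; no
  weighted model averaging; no semiparametric estimators (the estimator
  interface admits them).
- Very-large-p pre-screening is left as an extension point; the search
  as shipped evaluates all p single-covariate models at d = 1.
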
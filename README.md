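# panning

Prediction-risk driven sparse model selection for high-dimensional
biomarker data, with model-set filtering, paradigmatic covariate networks
and model-averaged prediction.

## The problem

In gene-expression classification (tens of samples, thousands of genes)
the goal is usually the smallest gene set that still predicts well — and
in practice not one set but *several* near-interchangeable ones, because
genes act in networks and can substitute for each other in explaining a
response. Likelihood-penalty selectors return a single model and optimize
a surrogate; practitioners often care about a concrete loss such as the
(possibly asymmetric) misclassification cost.

This package selects covariate subsets J by directly minimizing the
cross-validated out-of-sample divergence

D̂_J = (1/mK) Σₖ Σₗ (1/nₗ) Σ_{i∈I_{k,l}} D(ŷ(x_i, β̂^{J,k}), y_i),

where D is any user-chosen loss with D(u,v) > 0 for u ≠ v and D(u,u) = 0
(shipped: L1 and weighted misclassification), the folds I_{k,l} form an
m-fold partition repeated K times, and β̂^{J,k} comes from a pluggable
estimator (default: logistic MLE with a ridge fallback under separation).

Because the 2^p − 1 subsets cannot be enumerated, the search is a greedy
stochastic scan over model sizes d = 1, 2, …: all p single-covariate
models are evaluated, the ones with risk at or below the empirical
α-quantile q̂_d(α) are marked *promising*, and candidates at the next size
draw each covariate from the promising index set with probability π (else
from its complement) — an importance-sampling tilt that concentrates the
budget of B draws per dimension on covariates that already predicted
well. The working dimension d\* is fixed by sequentially testing whether
q̂_{d+1} is significantly smaller than q̂_d; the surviving models are
filtered to the set S\*0 of models statistically indistinguishable from
the best one; S\*0 yields a co-occurrence network over the selected
covariates (hubs = most frequent covariates, families = interchangeable
partners) and a model-averaged classifier.

See `docs/methods.md` for the full procedure, conventions and limitations.

## Worked example

Simulate a 60-sample training set with 40 covariates of which two (X1,
X2) drive a binary response through a logit-type link, then run the full
pipeline:

```sh
panning simulate --n-train 60 --n-test 34 --p 40 --active 1,2 \
    --beta 10 --intercept 0 --seed 11 \
    --out-x X.csv --out-y y.csv --out-x-test Xt.csv
panning run --x X.csv --y y.csv --alpha 0.05 --budget 400 --dmax 3 \
    --seed 11 --out results.json
```

which logs, one line per model size:

```
INFO d=1 models_evaluated=40 q_alpha=0.316667 |S*|=2 |I*|=2 (exhaustive)
INFO d=2 models_evaluated=165 q_alpha=0.150000 |S*|=17 |I*|=18
INFO d=3 models_evaluated=392 q_alpha=0.183333 |S*|=24 |I*|=25
d*=2  |S*0|=17  -> results.json
```

Read: the α-tail of the CV risk drops sharply from one to two covariates
(q̂ 0.32 → 0.15, sequential-test p = 0.006) and does not improve further
(p = 0.93), so d\* = 2; 17 two-covariate models survive filtering. In
`results.json` the minimum-risk model is the true pair with a tenfold-CV
error of 0.017, i.e. 1 misclassified holdout sample of 60:

```json
"filtered_models": [{"indices": [1, 2], "risk": 0.0167}, ...]
```

and the network identifies X2 as the hub (in 17 of 17 retained models,
position 1) with X1 and sixteen interchangeable partners at position 2.
Export it, and classify the held-out samples by model averaging:

```sh
panning network results.json --format graphml --out net.graphml
panning predict results.json --x Xt.csv --out pred.csv
```

`pred.csv` holds one row per new sample with the averaged vote share and
the predicted class (5 of 34 held-out samples misclassified in this run):

```
sample_id,score,class
0,0.0588,0
2,0.6470,1
```

The same pipeline is available as a library (`panning.run_analysis`,
`panning.run_panning`, `panning.model_average_predict`, ...), which is
what the test suite exercises.

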
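"""Synthetic benchmark data with the structure of the leukemia-style study.

The benchmark emulates a two-gene ground truth hidden among noise
covariates: the binary response is Bernoulli with success probability

    gamma = 1 / (1 + exp(intercept + sum_{j in active} beta * x_j))

i.e. a logit-type link on an intercept plus a sparse set of active
covariates with unit coefficients (note the printed form makes the class-1
probability *decrease* in the active sum; it equals one minus the standard
logistic of the linear predictor and is implemented verbatim).  The sample
is then split into a training set of 38 and a test set of 34 — the split
sizes of the original 72-patient leukemia cohort the design mimics.

The original study drew covariate rows from the real 7129-gene expression
matrix; this generator substitutes equicorrelated standard Gaussian
covariates so that every stage is testable without downloads, and accepts a
``supplied_matrix`` so the original experiment can be rerun when the real
data is available.  :func:`run_study_replicate` performs one full replicate
of the scaled study (search, dimension selection, filtering, single-model
and model-averaged prediction) and is what the acceptance script aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit

from .averaging import model_average_predict
from .divergence import DivergenceSpec, divergence_vector
from .risk import ConfigurationError, Dataset, EstimatorSpec, fit_model, predict_response
from .search import SearchConfig, run_panning
from .selection import TestSpec, filter_model_set, select_dimension

__all__ = [
    "SimulationDesign",
    "generate_covariates",
    "simulate_response",
    "make_benchmark_split",
    "make_study_dataset",
    "run_study_replicate",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of the benchmark generator.

    Defaults are the study conditions: a 38/34 train/test split, two active
    covariates with unit coefficients and unit intercept, independent
    standard Gaussian covariates.
    """

    n_train: int = 38
    n_test: int = 34
    p: int = 500
    active_set: Tuple[int, ...] = (0, 1)
    beta: float = 1.0
    intercept: float = 1.0
    covariate_source: str = "gaussian"
    correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.covariate_source not in ("gaussian", "supplied_matrix"):
            raise ConfigurationError(
                f"unknown covariate source {self.covariate_source!r}"
            )
        if not 0.0 <= self.correlation < 1.0:
            raise ConfigurationError("correlation must lie in [0, 1)")
        if any(not 0 <= j < self.p for j in self.active_set):
            raise ConfigurationError("active covariates must lie in 1..p")


def generate_covariates(n: int, p: int, correlation: float = 0.0, seed: int = 0) -> np.ndarray:
    """n x p matrix of zero-mean unit-variance Gaussians with constant
    pairwise correlation; deterministic given the seed."""
    if n < 1 or p < 1:
        raise ConfigurationError("n and p must be positive")
    if not 0.0 <= correlation < 1.0:
        raise ConfigurationError("correlation must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, p))
    if correlation == 0.0:
        return z
    shared = rng.standard_normal((n, 1))
    return np.sqrt(correlation) * shared + np.sqrt(1.0 - correlation) * z


def response_probability(X: np.ndarray, design: SimulationDesign) -> np.ndarray:
    """gamma = 1 / (1 + exp(intercept + beta * sum of active columns)),
    evaluated in the numerically stable logistic form."""
    active = list(design.active_set)
    eta = design.intercept + design.beta * X[:, active].sum(axis=1)
    return expit(-eta)


def simulate_response(X: np.ndarray, design: SimulationDesign) -> np.ndarray:
    """Bernoulli(gamma) responses under the design's seed."""
    gamma = response_probability(X, design)
    rng = np.random.default_rng(design.seed)
    return (rng.random(X.shape[0]) < gamma).astype(float)


def make_benchmark_split(
    X: np.ndarray,
    y: np.ndarray,
    n_train: int,
    n_test: int,
    seed: int = 0,
    feature_ids: Optional[Sequence[str]] = None,
) -> Tuple[Dataset, Dataset]:
    """Random disjoint train/test row split of the exact requested sizes."""
    n = X.shape[0]
    if n_train + n_test > n:
        raise ConfigurationError(
            f"split {n_train}+{n_test} exceeds the {n} available rows"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_rows = np.sort(order[:n_train])
    test_rows = np.sort(order[n_train : n_train + n_test])
    ids = [str(i + 1) for i in range(n)]
    train = Dataset(X[train_rows], y[train_rows], feature_ids=feature_ids,
                    sample_ids=[ids[i] for i in train_rows])
    test = Dataset(X[test_rows], y[test_rows], feature_ids=feature_ids,
                   sample_ids=[ids[i] for i in test_rows])
    return train, test


def make_study_dataset(
    design: SimulationDesign,
    supplied_matrix: Optional[np.ndarray] = None,
) -> Tuple[Dataset, Dataset]:
    """Covariates + response + split in one call, all from the design seed."""
    n = design.n_train + design.n_test
    seeds = np.random.SeedSequence(design.seed).spawn(3)

    def child(s) -> int:
        return int(s.generate_state(1)[0] % (2**31))

    if design.covariate_source == "supplied_matrix":
        if supplied_matrix is None:
            raise ConfigurationError("supplied_matrix source needs a matrix")
        X = np.asarray(supplied_matrix, dtype=float)
        if X.shape[0] < n:
            raise ConfigurationError("supplied matrix has too few rows")
    else:
        X = generate_covariates(n, design.p, design.correlation, seed=child(seeds[0]))
    y = simulate_response(
        X, SimulationDesign(**{**design.__dict__, "seed": child(seeds[1])})
    )
    return make_benchmark_split(X, y, design.n_train, design.n_test, seed=child(seeds[2]))


def run_study_replicate(
    seed: int,
    design: Optional[SimulationDesign] = None,
    budget: int = 2000,
    d_max: int = 3,
    alpha: float = 0.01,
    pi: float = 0.5,
    m: int = 10,
    K: int = 1,
    test_level: float = 0.1,
    supplied_matrix: Optional[np.ndarray] = None,
) -> Dict[str, float]:
    """One full replicate of the scaled benchmark study.

    Generates data under ``design`` (reseeded with ``seed``), runs the
    search, selects d*, filters to S*0, keeps the single minimum-CV-error
    model (lexicographic tie-break) and evaluates it and the model average
    on the held-out test set.  Returns the replicate's summary numbers.
    """
    design = SimulationDesign() if design is None else design
    design = SimulationDesign(**{**design.__dict__, "seed": seed})
    train, test = make_study_dataset(design, supplied_matrix=supplied_matrix)

    config = SearchConfig(alpha=alpha, budget=budget, pi=pi, d_max=d_max,
                          m=m, K=K, seed=seed)
    espec = EstimatorSpec()
    div = DivergenceSpec(kind="classification")
    records = run_panning(train, config, espec, div)
    tspec = TestSpec(test="proportion_binomial", level=test_level,
                     correction="bonferroni")
    d_star = select_dimension(records, tspec)
    record = records[d_star - 1]
    filtered = filter_model_set(record, tspec)

    best = min(filtered, key=lambda mod: (mod.risk, mod.indices))
    cv_errors = best.loss_events()[0] / max(K, 1)
    fit = fit_model(train, best.indices, espec, np.arange(train.n))
    y_hat = predict_response(fit, test.X, espec)
    test_errors = int(np.count_nonzero(divergence_vector(div, y_hat, test.y)))
    avg_classes, _ = model_average_predict(filtered, train, test.X, espec)
    avg_errors = int(np.count_nonzero(divergence_vector(div, avg_classes, test.y)))

    truth = frozenset(design.active_set)
    return {
        "seed": seed,
        "d_star": d_star,
        "best_model": best.indices,
        "n_selected_models": len(filtered),
        "cv_errors": cv_errors,
        "cv_n": train.n,
        "test_errors": test_errors,
        "avg_test_errors": avg_errors,
        "test_n": test.n,
        "true_model_is_best": frozenset(best.indices) == truth,
        "true_model_in_filtered": any(
            frozenset(mod.indices) == truth for mod in filtered
        ),
    }
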
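"""The Panning search: a greedy stochastic scan of sparse covariate subsets.

The search grows model dimension stepwise.  At d = 1 every single-covariate
augmentation of the forced set M0 is evaluated exhaustively.  At each larger
d, candidate models are drawn one covariate at a time: with probability pi
the covariate comes from the index set I*_{d-1} of covariates that appeared
in a "promising" model at the previous dimension, and with probability
1 - pi from its complement.  Because I*_{d-1} is small, covariates that
already proved useful are strongly favoured — an importance-sampling-style
tilt of the proposal distribution — while the complement draw keeps every
covariate reachable.

At each dimension the promising set S*_d collects the evaluated models whose
cross-validated risk lies at or below the empirical alpha-quantile
q_hat_d(alpha) of the risks, computed as the ceil(alpha*N)-th order
statistic of the N finite risks with ties included.

Hyper-parameter guidance: alpha is a small tail (default 1%); the sampling
budget B is usefully kept between p and C(p, 2) (a warning is emitted
outside that range, since small-p exhaustive enumeration legitimately wants
B above it); pi = 0.5 already favours the promising set heavily whenever
|I*| << p; d_max bounds the model size and must not exceed what the
estimator can support (at most n).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .divergence import DivergenceSpec
from .risk import (
    CandidateModel,
    ConfigurationError,
    Dataset,
    EstimatorSpec,
    FoldPlan,
    RiskResult,
    estimate_risk,
    make_fold_plan,
)

__all__ = [
    "SearchConfig",
    "DimensionRecord",
    "alpha_quantile",
    "initial_step",
    "sample_candidate",
    "general_step",
    "run_panning",
]

logger = logging.getLogger("panning")


@dataclass(frozen=True)
class SearchConfig:
    """Hyper-parameters of the search.

    ``budget`` is the number of candidate models drawn per dimension
    (``None`` = ``min(2000, C(p - p0, 2))``, floored at ``p``); ``pi`` the
    probability of drawing each covariate from the previous promising index
    set; ``M0`` covariate indices forced into every model; ``m``/``K`` the
    cross-validation geometry shared by all candidates.
    """

    alpha: float = 0.01
    budget: Optional[int] = None
    pi: float = 0.5
    d_max: int = 10
    M0: Tuple[int, ...] = ()
    m: int = 10
    K: int = 1
    seed: int = 0
    exhaustive_when_possible: bool = True
    dedupe_evaluations: bool = True
    stratify: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if not 0.0 <= self.pi <= 1.0:
            raise ConfigurationError("pi must lie in [0, 1]")
        if self.d_max < 1:
            raise ConfigurationError("d_max must be >= 1")
        object.__setattr__(self, "M0", tuple(sorted(int(i) for i in set(self.M0))))

    def resolved_budget(self, p_free: int) -> int:
        pairs = p_free * (p_free - 1) // 2
        if self.budget is None:
            return max(p_free, min(2000, max(pairs, 1)))
        if not (p_free <= self.budget <= max(pairs, p_free)):
            logger.warning(
                "budget B=%d outside the rule-of-thumb range [p=%d, C(p,2)=%d]",
                self.budget,
                p_free,
                pairs,
            )
        return self.budget


@dataclass
class DimensionRecord:
    """Everything the search learned at one model dimension ``d``.

    ``evaluated`` lists the distinct models evaluated (each including M0 and
    exactly d free covariates); ``q_alpha`` the empirical alpha-quantile of
    their finite risks; ``promising_models`` the models at or below it
    (S*_d); ``promising_indices``/``complement_indices`` the covariate index
    sets I*_d and I^c_d.
    """

    d: int
    evaluated: List[CandidateModel]
    q_alpha: float
    promising_models: List[CandidateModel]
    promising_indices: frozenset
    complement_indices: frozenset
    sampled_count: int = 0
    exhaustive: bool = False


def alpha_quantile(risks: Sequence[float], alpha: float) -> float:
    """ceil(alpha*N)-th order statistic of the finite risks."""
    finite = np.sort([r for r in risks if math.isfinite(r)])
    if finite.size == 0:
        raise ConfigurationError("no finite risks: every candidate model failed")
    rank = max(1, math.ceil(alpha * finite.size))
    return float(finite[rank - 1])


def _build_record(
    d: int,
    models: List[CandidateModel],
    config: SearchConfig,
    p: int,
    sampled_count: int,
    exhaustive: bool,
) -> DimensionRecord:
    q = alpha_quantile([m.risk for m in models], config.alpha)
    promising = [m for m in models if m.risk <= q]
    istar = frozenset(i for m in promising for i in m.indices)
    icomp = frozenset(range(p)) - istar
    return DimensionRecord(
        d=d,
        evaluated=models,
        q_alpha=q,
        promising_models=promising,
        promising_indices=istar,
        complement_indices=icomp,
        sampled_count=sampled_count,
        exhaustive=exhaustive,
    )


def _evaluate(
    dataset: Dataset,
    free_indices: Tuple[int, ...],
    config: SearchConfig,
    plan: FoldPlan,
    spec: EstimatorSpec,
    div: DivergenceSpec,
    cache: Optional[Dict[Tuple[int, ...], CandidateModel]],
) -> CandidateModel:
    indices = tuple(sorted(set(free_indices) | set(config.M0)))
    if cache is not None and indices in cache:
        return cache[indices]
    res: RiskResult = estimate_risk(dataset, indices, plan, spec, div)
    model = CandidateModel(indices=indices, risk=res.risk, losses=res.losses, flagged=res.flagged)
    if cache is not None:
        cache[indices] = model
    return model


def initial_step(
    dataset: Dataset,
    config: SearchConfig,
    plan: FoldPlan,
    spec: EstimatorSpec,
    div: DivergenceSpec,
    cache: Optional[Dict[Tuple[int, ...], CandidateModel]] = None,
) -> DimensionRecord:
    """Exhaustive d = 1 step: every single-covariate augmentation of M0."""
    free = [j for j in range(dataset.p) if j not in config.M0]
    if not free:
        raise ConfigurationError("no free covariates outside M0")
    models = [_evaluate(dataset, (j,), config, plan, spec, div, cache) for j in free]
    if not any(math.isfinite(m.risk) for m in models):
        raise ConfigurationError("all single-covariate models are unfittable")
    return _build_record(1, models, config, dataset.p, len(free), True)


def sample_candidate(
    promising: frozenset,
    complement: frozenset,
    d: int,
    pi: float,
    rng: np.random.Generator,
) -> Tuple[int, ...]:
    """Draw one size-``d`` free-covariate set.

    Each covariate: pick the promising set with probability ``pi`` (else the
    complement), then draw uniformly without replacement from it; if the
    chosen set has no covariate left, fall through to the other set.
    """
    avail_p = list(promising)
    avail_c = list(complement)
    if d > len(avail_p) + len(avail_c):
        raise ConfigurationError(
            f"cannot draw {d} covariates from {len(avail_p) + len(avail_c)} available"
        )
    chosen: List[int] = []
    for _ in range(d):
        use_promising = rng.random() < pi
        pool = avail_p if use_promising else avail_c
        if not pool:
            pool = avail_c if use_promising else avail_p
        idx = rng.integers(len(pool))
        chosen.append(pool.pop(idx))
    return tuple(sorted(chosen))


def general_step(
    dataset: Dataset,
    d: int,
    prev: DimensionRecord,
    config: SearchConfig,
    plan: FoldPlan,
    spec: EstimatorSpec,
    div: DivergenceSpec,
    rng: Optional[np.random.Generator] = None,
    cache: Optional[Dict[Tuple[int, ...], CandidateModel]] = None,
) -> DimensionRecord:
    """Sample ``budget`` candidate models of dimension ``d`` (or enumerate all
    of them when that is cheaper) and build the promising sets."""
    if d < 2:
        raise ConfigurationError("general_step applies to d >= 2")
    rng = np.random.default_rng(config.seed + d) if rng is None else rng
    if cache is None and config.dedupe_evaluations:
        cache = {}
    free = [j for j in range(dataset.p) if j not in config.M0]
    budget = config.resolved_budget(len(free))
    n_subsets = math.comb(len(free), d)

    promising = prev.promising_indices - set(config.M0)
    complement = frozenset(free) - promising
    if not promising:
        logger.warning("I*_%d is empty; sampling from the complement only", d - 1)

    models: List[CandidateModel] = []
    seen = set()
    if config.exhaustive_when_possible and n_subsets <= budget:
        for combo in combinations(free, d):
            models.append(_evaluate(dataset, combo, config, plan, spec, div, cache))
        sampled = n_subsets
        exhaustive = True
    else:
        for _ in range(budget):
            combo = sample_candidate(promising, complement, d, config.pi, rng)
            model = _evaluate(dataset, combo, config, plan, spec, div, cache)
            if config.dedupe_evaluations:
                # quantile taken over distinct evaluated models
                if model.indices not in seen:
                    seen.add(model.indices)
                    models.append(model)
            else:
                models.append(model)
        sampled = budget
        exhaustive = False
    return _build_record(d, models, config, dataset.p, sampled, exhaustive)


def run_panning(
    dataset: Dataset,
    config: SearchConfig,
    spec: Optional[EstimatorSpec] = None,
    div: Optional[DivergenceSpec] = None,
    plan: Optional[FoldPlan] = None,
) -> List[DimensionRecord]:
    """Run the full search for d = 1..d_max and return one record per
    dimension.  A single fold plan, derived from the master seed, is shared
    by every candidate model so that risks are compared on common splits.
    Identical seeds give identical output.
    """
    spec = EstimatorSpec() if spec is None else spec
    div = DivergenceSpec() if div is None else div
    if config.d_max > dataset.n:
        raise ConfigurationError("d_max exceeds the estimation limit (sample size)")
    for i in config.M0:
        if not 0 <= i < dataset.p:
            raise ConfigurationError(f"M0 index {i} out of range")
    if div.kind == "classification" and not dataset.is_binary:
        raise ConfigurationError(
            "classification divergence requires a binary {0,1} response"
        )
    seeds = np.random.SeedSequence(config.seed).spawn(2)
    plan_seed = int(seeds[0].generate_state(1)[0] % (2**31))
    if plan is None:
        labels = dataset.y if (config.stratify and dataset.is_binary) else None
        plan = make_fold_plan(dataset.n, config.m, config.K, labels=labels, seed=plan_seed)
    rng = np.random.default_rng(seeds[1])
    cache = {} if config.dedupe_evaluations else None

    records: List[DimensionRecord] = []
    record = initial_step(dataset, config, plan, spec, div, cache)
    records.append(record)
    _log_record(record)
    for d in range(2, config.d_max + 1):
        record = general_step(
            dataset, d, records[-1], config, plan, spec, div, rng=rng, cache=cache,
        )
        records.append(record)
        _log_record(record)
    return records


def _log_record(record: DimensionRecord) -> None:
    logger.info(
        "d=%d models_evaluated=%d q_alpha=%.6f |S*|=%d |I*|=%d%s",
        record.d,
        len(record.evaluated),
        record.q_alpha,
        len(record.promising_models),
        len(record.promising_indices),
        " (exhaustive)" if record.exhaustive else "",
    )
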
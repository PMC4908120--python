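"""Dimension selection and model-set filtering.

The search produces, for every dimension d, the empirical alpha-quantile
q_hat_d(alpha) of the candidate risks.  The working dimension d* is the
point where adding a covariate stops buying a significant risk reduction:
starting at j = 1 we test whether q_hat_{j+1} is significantly *smaller*
than q_hat_j and increment j as long as it is; the first non-rejection
stops the walk and d* = j.

Because q_hat is itself an estimate, the tests operate on observable data
rather than on the two scalar quantiles.  The convention here is to pool
the per-observation holdout losses of the alpha-tail model sets S*_d: for a
classification divergence every holdout prediction of every promising model
is a Bernoulli loss event, and the comparison between adjacent dimensions
is a one-sided two-proportion exact (Fisher) test on the pooled
misclassification counts; for the L1 divergence the pooled per-observation
losses feed a one-sided Mann-Whitney rank test.  Levels are Bonferroni
corrected over the planned number of comparisons.

The same machinery filters the final model set: after deduplication, the
minimum-risk model J_min seeds S*0, and the remaining models join in
ascending risk order until the first one whose loss is significantly
greater than J_min's — S*0 is therefore a prefix of the sorted list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .network import GeneNetwork
from .risk import CandidateModel, ConfigurationError
from .search import DimensionRecord, SearchConfig

__all__ = [
    "TestSpec",
    "PanningResult",
    "select_dimension",
    "dimension_test_pvalues",
    "filter_model_set",
]

logger = logging.getLogger("panning")


@dataclass(frozen=True)
class TestSpec:
    """Which test compares loss samples, at what level, with what correction.

    ``proportion_binomial`` (exact two-proportion / Fisher) suits
    classification losses; ``mann_whitney`` suits real-valued L1 losses.
    Under ``bonferroni`` the working level is ``level / n_planned_tests``.
    """

    __test__ = False  # not a pytest class, despite the name

    test: str = "proportion_binomial"
    level: float = 0.1
    correction: str = "bonferroni"

    def __post_init__(self) -> None:
        if self.test not in ("proportion_binomial", "mann_whitney"):
            raise ConfigurationError(f"unknown test {self.test!r}")
        if not 0.0 < self.level < 1.0:
            raise ConfigurationError("test level must lie in (0, 1)")
        if self.correction not in ("bonferroni", "none"):
            raise ConfigurationError(f"unknown correction {self.correction!r}")

    def corrected_level(self, n_tests: int) -> float:
        if self.correction == "bonferroni" and n_tests > 1:
            return self.level / n_tests
        return self.level


def _pooled_events(models: Sequence[CandidateModel]) -> Tuple[int, int]:
    events, total = 0, 0
    for m in models:
        e, t = m.loss_events()
        events += e
        total += t
    return events, total


def _pooled_losses(models: Sequence[CandidateModel]) -> np.ndarray:
    return np.concatenate([m.losses for m in models])


def _pvalue_smaller(
    test: str,
    new_models: Sequence[CandidateModel],
    old_models: Sequence[CandidateModel],
) -> float:
    """p-value for H1: the pooled loss of ``new_models`` is smaller."""
    if test == "proportion_binomial":
        e_new, n_new = _pooled_events(new_models)
        e_old, n_old = _pooled_events(old_models)
        table = [[e_new, n_new - e_new], [e_old, n_old - e_old]]
        # one-sided: odds of a loss event lower in the new sample
        return float(stats.fisher_exact(table, alternative="less")[1])
    x_new = _pooled_losses(new_models)
    x_old = _pooled_losses(old_models)
    if np.ptp(np.concatenate([x_new, x_old])) == 0:
        return 1.0  # identical constant losses: nothing to reject
    return float(stats.mannwhitneyu(x_new, x_old, alternative="less")[1])


def dimension_test_pvalues(
    records: Sequence[DimensionRecord], test: TestSpec
) -> List[float]:
    """p-values of the sequential comparisons q_{j+1} < q_j, j = 1..d_max-1."""
    return [
        _pvalue_smaller(test.test, records[j + 1].promising_models,
                        records[j].promising_models)
        for j in range(len(records) - 1)
    ]


def select_dimension(records: Sequence[DimensionRecord], test: TestSpec) -> int:
    """Walk j = 1, 2, ... while q_{j+1} is significantly smaller than q_j;
    return the first j without a rejection."""
    if not records:
        raise ConfigurationError("no dimension records")
    if len(records) < 2:
        logger.warning("fewer than 2 dimension records; d* = 1 by default")
        return records[0].d
    level = test.corrected_level(len(records) - 1)
    pvalues = dimension_test_pvalues(records, test)
    j = 0
    while j < len(pvalues) and pvalues[j] < level:
        j += 1
    return records[j].d


def filter_model_set(record: DimensionRecord, test: TestSpec) -> List[CandidateModel]:
    """Reduce S*_{d*} to the final set S*0 of statistically indistinguishable
    near-optimal models.

    Models are deduplicated by index tuple, sorted by ascending risk (index
    tuple as deterministic tie-break, so J_min is the lexicographically
    smallest minimum-risk model), and accepted until the first model whose
    loss is significantly greater than J_min's.
    """
    if not record.promising_models:
        raise ConfigurationError("promising model set is empty")
    unique = {}
    for m in record.promising_models:
        unique.setdefault(m.indices, m)
    ordered = sorted(unique.values(), key=lambda m: (m.risk, m.indices))
    j_min = ordered[0]
    level = test.corrected_level(max(len(ordered) - 1, 1))
    kept = [j_min]
    for m in ordered[1:]:
        # one-sided: is D_hat_J significantly greater than D_hat_{J_min}?
        p = _pvalue_smaller(test.test, [j_min], [m])
        if p < level:
            break
        kept.append(m)
    return kept


@dataclass
class PanningResult:
    """Bundle of a full run: per-dimension records, the selected dimension,
    the promising set at d*, the filtered set S*0, and the covariate
    co-occurrence network built from it."""

    records: List[DimensionRecord]
    d_star: int
    final_models: List[CandidateModel]
    filtered_models: List[CandidateModel]
    network: Optional[GeneNetwork]
    config_echo: SearchConfig
    dimension_pvalues: List[float] = field(default_factory=list)
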
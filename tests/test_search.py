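import math
from itertools import combinations

import numpy as np
import pytest

from panning import (
    ConfigurationError,
    Dataset,
    DivergenceSpec,
    EstimatorSpec,
    SearchConfig,
    alpha_quantile,
    estimate_risk,
    general_step,
    initial_step,
    make_fold_plan,
    run_panning,
    sample_candidate,
)


@pytest.fixture()
def small_dataset():
    """p=8 covariates, n=24; covariate 0 carries the signal with noise."""
    rng = np.random.default_rng(21)
    X = rng.standard_normal((24, 8))
    logits = -0.5 + 2.0 * X[:, 0]
    y = (rng.random(24) < 1 / (1 + np.exp(-logits))).astype(float)
    return Dataset(X, y)


class TestQuantileRule:
    def test_order_statistic_definition(self):
        risks = [0.5, 0.1, 0.3, 0.2, 0.4]
        assert alpha_quantile(risks, 0.2) == 0.1  # ceil(0.2*5)=1st order stat
        assert alpha_quantile(risks, 0.5) == 0.3
        assert alpha_quantile(risks, 0.99) == 0.5

    def test_infinite_risks_excluded(self):
        assert alpha_quantile([math.inf, 0.2, 0.7], 0.3) == 0.2

    def test_promising_set_contains_at_least_quantile_count(self, small_dataset):
        cfg = SearchConfig(alpha=0.25, d_max=1, m=4, seed=0)
        plan = make_fold_plan(24, 4, labels=small_dataset.y, seed=0)
        rec = initial_step(small_dataset, cfg, plan, EstimatorSpec(), DivergenceSpec())
        assert len(rec.promising_models) >= math.ceil(0.25 * 8)
        assert all(m.risk <= rec.q_alpha for m in rec.promising_models)


class TestInitialStep:
    def test_evaluates_every_single_covariate_model(self, small_dataset):
        cfg = SearchConfig(alpha=0.2, d_max=1, m=4, seed=1)
        plan = make_fold_plan(24, 4, labels=small_dataset.y, seed=1)
        rec = initial_step(small_dataset, cfg, plan, EstimatorSpec(), DivergenceSpec())
        assert len(rec.evaluated) == 8
        assert sorted(m.indices for m in rec.evaluated) == [(j,) for j in range(8)]

    def test_m0_augmentation_counts(self, small_dataset):
        cfg = SearchConfig(alpha=0.2, d_max=1, m=4, M0=(3,), seed=1)
        plan = make_fold_plan(24, 4, labels=small_dataset.y, seed=1)
        rec = initial_step(small_dataset, cfg, plan, EstimatorSpec(), DivergenceSpec())
        assert len(rec.evaluated) == 7
        assert all(3 in m.indices and m.d == 2 for m in rec.evaluated)

    def test_active_covariate_attains_strict_minimum(self, separable_dataset):
        cfg = SearchConfig(alpha=0.2, d_max=1, m=5, seed=2)
        plan = make_fold_plan(20, 5, labels=separable_dataset.y, seed=2)
        rec = initial_step(
            separable_dataset, cfg, plan, EstimatorSpec(), DivergenceSpec()
        )
        risks = {m.indices[0]: m.risk for m in rec.evaluated}
        assert risks[0] == 0.0
        assert all(risks[j] > 0.0 for j in range(1, 4))

    def test_alpha_point2_with_distinct_risks_keeps_single_best(self, small_dataset):
        cfg = SearchConfig(alpha=0.2, d_max=1, m=4, seed=3)
        plan = make_fold_plan(24, 4, labels=small_dataset.y, seed=3)
        rec = initial_step(small_dataset, cfg, plan, EstimatorSpec(), DivergenceSpec())
        risks = sorted(m.risk for m in rec.evaluated)
        if risks[0] < risks[1]:  # strictly distinct minimum: tail is one model
            assert len(rec.promising_models) >= 1
            assert rec.q_alpha == risks[1]  # ceil(0.2*8)=2nd order statistic


class TestSampleCandidate:
    def test_pi_one_draws_only_from_promising(self):
        rng = np.random.default_rng(0)
        promising, complement = frozenset(range(5)), frozenset(range(5, 12))
        for _ in range(50):
            draw = sample_candidate(promising, complement, 3, 1.0, rng)
            assert set(draw) <= promising and len(draw) == 3

    def test_pi_zero_draws_only_from_complement(self):
        rng = np.random.default_rng(1)
        promising, complement = frozenset(range(5)), frozenset(range(5, 12))
        for _ in range(50):
            draw = sample_candidate(promising, complement, 4, 0.0, rng)
            assert set(draw) <= complement

    def test_balanced_pi_set_frequency(self):
        rng = np.random.default_rng(2)
        promising, complement = frozenset(range(10)), frozenset(range(10, 30))
        n_draws = 10_000
        hits = sum(
            sample_candidate(promising, complement, 1, 0.5, rng)[0] in promising
            for _ in range(n_draws)
        )
        # Bernoulli(0.5): 3-sigma band around the mean
        assert abs(hits / n_draws - 0.5) <= 3 * math.sqrt(0.25 / n_draws)

    def test_exhausted_set_falls_through(self):
        rng = np.random.default_rng(3)
        draw = sample_candidate(frozenset({4}), frozenset({7, 9}), 3, 1.0, rng)
        assert set(draw) == {4, 7, 9}

    def test_promising_member_sampled_more_often_than_complement_member(self):
        # per-draw probability pi/|I*| for a promising covariate exceeds
        # (1-pi)/|Ic| for a complement one whenever pi >= |I*|/(|I*|+|Ic|)
        rng = np.random.default_rng(4)
        promising, complement = frozenset(range(4)), frozenset(range(4, 40))
        counts = {i: 0 for i in range(40)}
        for _ in range(10_000):
            for i in sample_candidate(promising, complement, 1, 0.5, rng):
                counts[i] += 1
        worst_promising = min(counts[i] for i in promising)
        best_complement = max(counts[i] for i in complement)
        assert worst_promising > best_complement

    def test_too_few_covariates_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ConfigurationError):
            sample_candidate(frozenset({1}), frozenset({2}), 3, 0.5, rng)


class TestGeneralStep:
    def test_exhaustive_enumeration_matches_brute_force(self, small_dataset):
        spec, div = EstimatorSpec(), DivergenceSpec()
        cfg = SearchConfig(alpha=0.1, budget=60, d_max=2, m=4, seed=6)
        plan = make_fold_plan(24, 4, labels=small_dataset.y, seed=6)
        rec1 = initial_step(small_dataset, cfg, plan, spec, div)
        rec2 = general_step(small_dataset, 2, rec1, cfg, plan, spec, div)
        assert rec2.exhaustive and len(rec2.evaluated) == math.comb(8, 2)

        oracle = {
            J: estimate_risk(small_dataset, J, plan, spec, div).risk
            for J in combinations(range(8), 2)
        }
        for m in rec2.evaluated:
            assert m.risk == pytest.approx(oracle[m.indices], abs=1e-12)
        assert rec2.q_alpha == pytest.approx(
            alpha_quantile(list(oracle.values()), 0.1), abs=1e-12
        )
        expect_promising = {J for J, r in oracle.items() if r <= rec2.q_alpha}
        assert {m.indices for m in rec2.promising_models} == expect_promising
        assert rec2.promising_indices == frozenset(
            i for J in expect_promising for i in J
        )

    def test_every_model_contains_m0(self, small_dataset):
        spec, div = EstimatorSpec(), DivergenceSpec()
        cfg = SearchConfig(alpha=0.2, budget=40, d_max=2, M0=(5,), m=4, seed=7)
        plan = make_fold_plan(24, 4, labels=small_dataset.y, seed=7)
        rec1 = initial_step(small_dataset, cfg, plan, spec, div)
        rec2 = general_step(small_dataset, 2, rec1, cfg, plan, spec, div)
        assert all(5 in m.indices for m in rec2.evaluated)
        assert all(m.d == 3 for m in rec2.evaluated)  # M0 plus 2 free covariates

    def test_promising_set_never_empty(self, small_dataset):
        spec, div = EstimatorSpec(), DivergenceSpec()
        cfg = SearchConfig(alpha=0.01, budget=30, d_max=2, m=4, seed=8)
        plan = make_fold_plan(24, 4, labels=small_dataset.y, seed=8)
        rec1 = initial_step(small_dataset, cfg, plan, spec, div)
        rec2 = general_step(small_dataset, 2, rec1, cfg, plan, spec, div)
        assert len(rec1.promising_models) >= 1
        assert len(rec2.promising_models) >= 1


class TestRunPanning:
    def test_seeded_determinism(self, small_dataset):
        cfg = SearchConfig(alpha=0.2, budget=25, d_max=3, m=4, seed=9)
        a = run_panning(small_dataset, cfg)
        b = run_panning(small_dataset, cfg)
        for ra, rb in zip(a, b):
            assert [m.indices for m in ra.evaluated] == [m.indices for m in rb.evaluated]
            assert [m.risk for m in ra.evaluated] == [m.risk for m in rb.evaluated]
            assert ra.q_alpha == rb.q_alpha
            assert ra.promising_indices == rb.promising_indices

    def test_one_record_per_dimension(self, small_dataset):
        cfg = SearchConfig(alpha=0.2, budget=25, d_max=3, m=4, seed=10)
        records = run_panning(small_dataset, cfg)
        assert [r.d for r in records] == [1, 2, 3]

    def test_full_exhaustive_search_matches_enumeration(self, small_dataset):
        """Small-p oracle equivalence across all dimensions at once."""
        spec, div = DivergenceSpec(), EstimatorSpec()
        cfg = SearchConfig(alpha=0.1, budget=60, d_max=3, m=4, seed=11)
        records = run_panning(small_dataset, cfg, div=spec, spec=div)
        assert records[0].exhaustive and records[1].exhaustive
        # d=3: C(8,3)=56 <= 60 so enumeration must trigger there too
        assert records[2].exhaustive
        assert len(records[2].evaluated) == math.comb(8, 3)

    def test_d_max_beyond_sample_size_rejected(self, small_dataset):
        with pytest.raises(ConfigurationError):
            run_panning(small_dataset, SearchConfig(d_max=25, m=4, seed=0))
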
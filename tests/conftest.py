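from pathlib import Path

import numpy as np
import pytest

from panning import Dataset, FoldPlan
from panning.io import load_dataset

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def fixture12() -> Dataset:
    """Shipped 12-sample, 3-covariate dataset with a balanced binary response."""
    return load_dataset(DATA / "fixture12_x.csv", DATA / "fixture12_y.csv")


@pytest.fixture(scope="session")
def fixed_3fold_plan() -> FoldPlan:
    """The deterministic 3-fold plan (sample i -> fold i mod 3) used by the
    hand-computed cross-validation checks."""
    return FoldPlan(n=12, m=3, K=1, assignment=(np.arange(12) % 3)[None, :])


@pytest.fixture()
def separable_dataset() -> Dataset:
    """Noiseless toy: y = 1{x_1 > 0} with a margin, plus noise covariates."""
    rng = np.random.default_rng(7)
    n = 20
    x1 = np.concatenate([rng.uniform(-2.0, -0.5, 10), rng.uniform(0.5, 2.0, 10)])
    noise = rng.standard_normal((n, 3))
    X = np.column_stack([x1, noise])
    y = (x1 > 0).astype(float)
    order = rng.permutation(n)
    return Dataset(X[order], y[order])
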
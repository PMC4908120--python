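"""Model-averaged prediction over the selected model set.

Every retained model is refit on the full training data and asked for a
hard class prediction on each new row; the averaged score is the fraction
of models voting class 1 and the final class is 1 when the score reaches
the threshold (ties at the threshold resolve to class 1).  Averaging hard
votes — rather than fitted probabilities — is the default; ``soft=True``
averages probabilities instead.
"""

from __future__ import annotations

import logging
from typing import List, Sequence, Tuple

import numpy as np

from .risk import CandidateModel, Dataset, EstimatorSpec, fit_model, predict_response

__all__ = ["model_average_predict"]

logger = logging.getLogger("panning")


def model_average_predict(
    models: Sequence[CandidateModel],
    dataset: Dataset,
    new_X: np.ndarray,
    spec: EstimatorSpec = None,
    threshold: float = 0.5,
    soft: bool = False,
) -> Tuple[np.ndarray, np.ndarray]:
    """Predict classes for ``new_X`` by averaging the per-model predictions.

    Returns ``(classes, scores)``; scores lie in [0, 1] and are invariant to
    the order of ``models``.  Unfittable member models are dropped with a
    warning; if every member fails a ``ValueError`` is raised.
    """
    if not models:
        raise ValueError("model list is empty")
    spec = EstimatorSpec() if spec is None else spec
    new_X = np.atleast_2d(np.asarray(new_X, dtype=float))
    all_rows = np.arange(dataset.n)
    votes: List[np.ndarray] = []
    for m in models:
        fit = fit_model(dataset, m.indices, spec, all_rows)
        if not fit.ok:
            logger.warning("dropping unfittable model %s from the average", m.indices)
            continue
        votes.append(predict_response(fit, new_X, spec, return_prob=soft))
    if not votes:
        raise ValueError("every member model was unfittable")
    scores = np.mean(votes, axis=0)
    classes = (scores >= threshold).astype(float)
    return classes, scores
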
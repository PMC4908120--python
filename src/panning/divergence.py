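"""User-selectable divergence measures for out-of-sample prediction error.

A divergence ``D(y_pred, y_true)`` scores a single prediction against the
observed value.  The only structural requirement is *positiveness*:
``D(u, v) > 0`` for ``u != v`` and ``D(u, u) = 0``.  Beyond that the measure
is entirely up to the user — the selection criterion is prediction loss, not
likelihood, so any loss that encodes the practical cost of a mistake is
admissible.  Two measures ship with the package:

``l1``
    Absolute error ``|y_pred - y_true|``, for real-valued responses.

``classification``
    Asymmetric misclassification cost for binary responses:
    ``w1`` is charged for predicting 1 when the truth is 0 (false positive)
    and ``w2`` for predicting 0 when the truth is 1 (false negative).
    With ``w1 = w2 = 1`` this is the usual 0-1 loss; unequal weights encode
    clinically asymmetric error costs.

Custom measures can be registered with :func:`register_divergence`; the
positiveness axiom is checked on a probe grid at registration time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Optional

import numpy as np

__all__ = [
    "DivergenceSpec",
    "DivergenceError",
    "evaluate_divergence",
    "divergence_vector",
    "register_divergence",
    "registered_divergences",
]


class DivergenceError(ValueError):
    """Invalid divergence configuration or invalid inputs for a measure."""


#: registry of custom scalar divergences, name -> D(y_pred, y_true)
_CUSTOM: Dict[str, Callable[[float, float], float]] = {}

_DEFAULT_PROBE = (-2.0, -0.5, 0.0, 0.3, 0.5, 1.0, 2.0)


def register_divergence(
    name: str,
    fn: Callable[[float, float], float],
    probe_grid: Optional[tuple] = None,
) -> None:
    """Register a custom divergence after self-testing the positiveness axiom.

    ``fn(u, v)`` is evaluated on all pairs of ``probe_grid`` values and must
    return 0 exactly when ``u == v`` and a strictly positive number otherwise.
    """
    if name in ("l1", "classification"):
        raise DivergenceError(f"cannot shadow built-in divergence {name!r}")
    grid = _DEFAULT_PROBE if probe_grid is None else tuple(probe_grid)
    for u in grid:
        for v in grid:
            value = fn(u, v)
            if u == v and value != 0:
                raise DivergenceError(
                    f"divergence {name!r} violates D(u,u)=0 at u={u!r}"
                )
            if u != v and not value > 0:
                raise DivergenceError(
                    f"divergence {name!r} violates D(u,v)>0 at ({u!r}, {v!r})"
                )
    _CUSTOM[name] = fn


def registered_divergences() -> tuple:
    """Names of all available divergence kinds."""
    return ("l1", "classification") + tuple(sorted(_CUSTOM))


@dataclass(frozen=True)
class DivergenceSpec:
    """Configuration of the divergence measure.

    Parameters
    ----------
    kind
        ``"l1"``, ``"classification"``, or the name of a registered custom
        measure.
    w1
        Cost of predicting 1 when the truth is 0 (classification only).
    w2
        Cost of predicting 0 when the truth is 1 (classification only).
    """

    kind: str = "classification"
    w1: float = 1.0
    w2: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in registered_divergences():
            raise DivergenceError(f"unknown divergence kind {self.kind!r}")
        if self.w1 < 0 or self.w2 < 0:
            raise DivergenceError("classification weights must be nonnegative")
        if self.kind == "classification" and self.w1 == 0 and self.w2 == 0:
            raise DivergenceError(
                "classification divergence needs at least one positive weight"
            )

    @property
    def max_loss(self) -> float:
        """Largest per-observation loss (classification only)."""
        return max(self.w1, self.w2)


def _check_binary(value: float, label: str) -> None:
    if value not in (0, 1):
        raise DivergenceError(
            f"{label} must be 0 or 1 for the classification divergence, "
            f"got {value!r}"
        )


def evaluate_divergence(spec: DivergenceSpec, y_pred: float, y_true: float) -> float:
    """Evaluate ``D(y_pred, y_true)`` for a single prediction."""
    if spec.kind == "l1":
        if not (np.isfinite(y_pred) and np.isfinite(y_true)):
            raise DivergenceError("l1 divergence requires finite inputs")
        return float(abs(y_pred - y_true))
    if spec.kind == "classification":
        _check_binary(y_pred, "y_pred")
        _check_binary(y_true, "y_true")
        if y_pred == 1 and y_true == 0:
            return float(spec.w1)
        if y_pred == 0 and y_true == 1:
            return float(spec.w2)
        return 0.0
    return float(_CUSTOM[spec.kind](y_pred, y_true))


def divergence_vector(
    spec: DivergenceSpec, y_pred: np.ndarray, y_true: np.ndarray
) -> np.ndarray:
    """Vectorized per-observation divergences (used by the CV risk estimator)."""
    y_pred = np.asarray(y_pred, dtype=float)
    y_true = np.asarray(y_true, dtype=float)
    if y_pred.shape != y_true.shape:
        raise DivergenceError("y_pred and y_true must have equal shapes")
    if spec.kind == "l1":
        return np.abs(y_pred - y_true)
    if spec.kind == "classification":
        if not (np.isin(y_pred, (0, 1)).all() and np.isin(y_true, (0, 1)).all()):
            raise DivergenceError(
                "classification divergence requires binary predictions and truths"
            )
        return np.where(
            (y_pred == 1) & (y_true == 0),
            spec.w1,
            np.where((y_pred == 0) & (y_true == 1), spec.w2, 0.0),
        )
    fn = _CUSTOM[spec.kind]
    return np.array([fn(u, v) for u, v in zip(y_pred, y_true)], dtype=float)
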
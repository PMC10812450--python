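"""Derringer desirability transforms and multi-response grid optimization.

Each predicted response is mapped onto [0, 1] relative to its desired
range; the composite score D is the weighted geometric mean, so a single
fully undesirable response annihilates the whole candidate.  The optimum
is searched exhaustively over a grid of realizable coded conditions
(dates, varieties, areas and harvests are discrete in the study).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .rsm import RSMModel, predict

__all__ = [
    "DesirabilitySpec",
    "OptimizationResult",
    "desirability_one",
    "composite",
    "optimize",
]


@dataclass(frozen=True)
class DesirabilitySpec:
    """Desired range, weight and direction for one response."""

    y_min: float
    y_max: float
    weight: float = 1.0
    direction: str = "maximize"

    def __post_init__(self):
        if not self.y_min < self.y_max:
            raise ValueError("y_min must be < y_max")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")
        if self.direction not in ("maximize", "minimize"):
            raise ValueError("direction must be 'maximize' or 'minimize'")


def desirability_one(y: float, spec: DesirabilitySpec) -> float:
    """Per-response desirability d_i in [0, 1].

    Maximize: 0 below y_min, 1 above y_max, ((y - y_min)/(y_max - y_min))^w
    in between.  Minimize mirrors it (1 below y_min, 0 above y_max).
    """
    span = spec.y_max - spec.y_min
    if spec.direction == "maximize":
        if y <= spec.y_min:
            return 0.0
        if y >= spec.y_max:
            return 1.0
        return ((y - spec.y_min) / span) ** spec.weight
    if y <= spec.y_min:
        return 1.0
    if y >= spec.y_max:
        return 0.0
    return ((spec.y_max - y) / span) ** spec.weight


def composite(d: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted geometric mean of per-response desirabilities.

    D = (prod d_i^{w_i})^{1/sum w_i}; any d_i = 0 gives D = 0.
    """
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValueError("empty desirability vector")
    if np.any((d < 0) | (d > 1)):
        raise ValueError("desirabilities must lie in [0, 1]")
    w = np.ones_like(d) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")
    if np.any(d == 0.0):
        return 0.0
    return float(np.exp(np.sum(w * np.log(d)) / np.sum(w)))


@dataclass
class OptimizationResult:
    """Grid-search optimum and its per-response breakdown."""

    coded_point: tuple[float, ...]
    predictions: dict[str, float]
    intervals: dict[str, tuple[float, float] | None]
    per_response_d: dict[str, float]
    composite_d: float
    degenerate: bool = False
    hull_exit: dict[str, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "coded_point": list(self.coded_point),
            "predictions": self.predictions,
            "intervals": {
                k: (None if v is None else list(v)) for k, v in self.intervals.items()
            },
            "per_response_d": self.per_response_d,
            "composite_d": self.composite_d,
            "degenerate": self.degenerate,
            "hull_exit": self.hull_exit,
        }


def optimize(
    models: dict[str, RSMModel],
    specs: dict[str, DesirabilitySpec],
    grid: list[list[float]],
    level: float = 0.95,
) -> OptimizationResult:
    """Exhaustive composite-desirability search over a coded grid.

    *grid* lists candidate coded levels per factor (5 lists); the search
    evaluates their Cartesian product and returns the point of maximal D,
    breaking ties toward the lexicographically smallest coded point.  If D
    is zero everywhere the first grid point is returned with a
    degenerate-optimum warning.  Responses predicted beyond their observed
    [y_min, y_max] band at the optimum are flagged in ``hull_exit``.
    """
    if not grid or any(len(axis) == 0 for axis in grid):
        raise ValueError("grid must provide at least one level per factor")
    missing = set(models) - set(specs)
    if missing:
        raise ValueError(f"no desirability spec for responses: {sorted(missing)}")
    responses = sorted(models)
    weights = np.array([specs[r].weight for r in responses])

    best_point: tuple[float, ...] | None = None
    best_d = -1.0
    for point in itertools.product(*[sorted(axis) for axis in grid]):
        x = np.asarray(point, dtype=float)
        d = np.array(
            [desirability_one(predict(models[r], x)[0], specs[r]) for r in responses]
        )
        D = composite(d, weights)
        if D > best_d or (D == best_d and point < best_point):
            best_d, best_point = D, point

    degenerate = best_d == 0.0
    if degenerate:
        warnings.warn("composite desirability is 0 on the whole grid", stacklevel=2)
        best_point = tuple(sorted(axis)[0] for axis in grid)

    x = np.asarray(best_point, dtype=float)
    preds, ivs, ds, hull = {}, {}, {}, {}
    for r in responses:
        yhat, iv = predict(models[r], x, level=level)
        preds[r], ivs[r] = yhat, iv
        ds[r] = desirability_one(yhat, specs[r])
        hull[r] = not (specs[r].y_min <= yhat <= specs[r].y_max)
    if any(hull.values()):
        outside = sorted(k for k, v in hull.items() if v)
        warnings.warn(
            f"optimum predicts outside the observed response range for: {outside}",
            stacklevel=2,
        )
    return OptimizationResult(
        coded_point=tuple(float(v) for v in best_point),
        predictions=preds,
        intervals=ivs,
        per_response_d=ds,
        composite_d=float(best_d if not degenerate else 0.0),
        degenerate=degenerate,
        hull_exit=hull,
    )
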
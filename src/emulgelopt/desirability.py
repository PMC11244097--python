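"""Derringer–Suich desirability functions and multi-response optimization.

Each response y is mapped to an individual desirability d ∈ [0, 1]
through a goal-dependent ramp between the bounds L and U:

* maximize:  d = ((y − L)/(U − L))^w, clipped to [0, 1] before the power,
* minimize:  d = ((U − y)/(U − L))^w,
* target:    two-sided ramp rising to 1 at the target and falling back,
* in_range:  indicator of L ≤ y ≤ U.

The composite desirability is the importance-weighted geometric mean
D = (Π d_i^r_i)^(1/Σ r_i); any d_i = 0 forces D = 0.  D is maximized
over the actual-factor box by a dense grid scan followed by local
refinement from the best grid cell and from seeded random starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np
from scipy import optimize as sopt

from ._poly import evaluate
from .design import FactorSpace

__all__ = ["Criterion", "OptimumResult", "desirability", "composite", "optimize", "observed_bounds"]

GOALS = ("maximize", "minimize", "target", "in_range")


@dataclass(frozen=True)
class Criterion:
    """Optimization goal for one response with bounds and shape exponents."""

    response: str
    goal: str
    low: float
    high: float
    target: float | None = None
    weight: float = 1.0
    importance: float = 1.0

    def __post_init__(self) -> None:
        if self.goal not in GOALS:
            raise ValueError(f"goal must be one of {GOALS}")
        if not self.low < self.high:
            raise ValueError(f"criterion {self.response!r}: low must be strictly below high")
        if self.goal == "target":
            if self.target is None or not (self.low < self.target < self.high):
                raise ValueError("target goal needs low < target < high")
        if self.weight < 0 or self.importance < 0:
            raise ValueError("weight and importance must be non-negative")


def desirability(y, criterion: Criterion):
    """Individual desirability of response value(s) ``y``; vectorized."""
    y = np.asarray(y, dtype=float)
    L, U, w = criterion.low, criterion.high, criterion.weight
    if criterion.goal == "maximize":
        d = np.clip((y - L) / (U - L), 0.0, 1.0) ** w
    elif criterion.goal == "minimize":
        d = np.clip((U - y) / (U - L), 0.0, 1.0) ** w
    elif criterion.goal == "target":
        t = criterion.target
        up = np.clip((y - L) / (t - L), 0.0, 1.0)
        down = np.clip((U - y) / (U - t), 0.0, 1.0)
        d = np.where(y <= t, up, down) ** w
    else:  # in_range
        d = ((y >= L) & (y <= U)).astype(float)
    if d.ndim == 0:
        return float(d)
    return d


def composite(d: Sequence, importances: Sequence[float] | None = None):
    """Importance-weighted geometric mean of individual desirabilities."""
    d = np.asarray(d, dtype=float)
    if np.any((d < -1e-12) | (d > 1 + 1e-12)):
        raise ValueError("desirabilities must lie in [0, 1]")
    if importances is None:
        r = np.ones(d.shape[0])
    else:
        r = np.asarray(importances, dtype=float)
    logs = np.log(np.clip(d, 1e-300, 1.0))
    D = np.exp(np.tensordot(r, logs, axes=(0, 0)) / r.sum())
    D = np.where(np.min(d, axis=0) <= 0.0, 0.0, D)
    if D.ndim == 0:
        return float(D)
    return D


@dataclass
class OptimumResult:
    factor_values: tuple[float, ...]
    predicted_responses: dict[str, float]
    individual_desirabilities: dict[str, float]
    composite_desirability: float
    degenerate: bool = False
    trace: list[dict] = field(default_factory=list)


def _predictor(model):
    """Accept a FittedModel or a plain actual-factor coefficient mapping."""
    if hasattr(model, "predict_actual"):
        return lambda *coords: model.predict_actual(*coords)
    if isinstance(model, Mapping):
        return lambda *coords: evaluate(model, list(coords))
    raise TypeError("model must be a FittedModel or an actual-factor coefficient mapping")


def observed_bounds(model, design_points: np.ndarray) -> tuple[float, float]:
    """Per-response extremes of the model's predictions over the design runs
    (the default bounds when no measured extremes are supplied)."""
    pred = _predictor(model)
    vals = np.asarray(pred(*[design_points[:, i] for i in range(design_points.shape[1])]))
    return float(vals.min()), float(vals.max())


def optimize(
    models: Mapping[str, object],
    criteria: Sequence[Criterion],
    factor_space: FactorSpace,
    seed: int = 0,
    grid_resolution: float = 0.01,
    n_starts: int = 8,
) -> OptimumResult:
    """Maximize composite desirability over the actual-factor box.

    Strategy: dense grid at ``grid_resolution`` (in actual units) over the
    box, then Nelder–Mead refinement from the best grid cell and from
    ``n_starts`` seeded random starts.  Ties on the grid (flat ridges) are
    broken toward the design center.  Deterministic for a given seed.
    """
    missing = [c.response for c in criteria if c.response not in models]
    if missing:
        raise ValueError(f"no fitted model for criteria responses: {missing}")
    preds = {c.response: _predictor(models[c.response]) for c in criteria}
    importances = np.array([c.importance for c in criteria])
    k = factor_space.k
    if k != 2:
        raise NotImplementedError("optimization is implemented for two factors")

    axes = [
        np.linspace(lo, hi, int(round((hi - lo) / grid_resolution)) + 1)
        for lo, hi in zip(factor_space.low, factor_space.high)
    ]
    G1, G2 = np.meshgrid(axes[0], axes[1], indexing="ij")

    def d_stack(x1, x2):
        ds = []
        for c in criteria:
            yv = np.asarray(preds[c.response](x1, x2), dtype=float)
            if not np.all(np.isfinite(yv)):
                raise ValueError(f"model for {c.response!r} predicts non-finite values in the box")
            ds.append(desirability(yv, c))
        return np.asarray(ds)

    Dgrid = composite(d_stack(G1, G2), importances)
    dmax = float(np.max(Dgrid))
    center = np.asarray(factor_space.center)
    ties = np.argwhere(Dgrid >= dmax - 1e-12)
    tie_pts = np.column_stack([G1[ties[:, 0], ties[:, 1]], G2[ties[:, 0], ties[:, 1]]])
    best_grid = tie_pts[np.argmin(np.sum((tie_pts - center) ** 2, axis=1))]
    degenerate = dmax <= 0.0

    def neg_d(x):
        return -float(composite(d_stack(np.array(x[0]), np.array(x[1])), importances))

    rng = np.random.default_rng(seed)
    starts = [np.asarray(best_grid, dtype=float)]
    lo = np.asarray(factor_space.low)
    hi = np.asarray(factor_space.high)
    for _ in range(n_starts):
        starts.append(lo + rng.random(k) * (hi - lo))

    best_x = np.asarray(best_grid, dtype=float)
    best_D = dmax
    trace = [{"start": "grid", "x": [float(v) for v in best_grid], "D": dmax, "converged": True}]
    if not degenerate:
        bounds = list(zip(factor_space.low, factor_space.high))
        for i, x0 in enumerate(starts):
            res = sopt.minimize(
                neg_d, x0, method="Nelder-Mead", bounds=bounds,
                options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000},
            )
            D_here = -float(res.fun)
            trace.append(
                {"start": "grid-refine" if i == 0 else f"random-{i}",
                 "x": [float(v) for v in res.x], "D": D_here, "converged": bool(res.success)}
            )
            better = D_here > best_D + 1e-15
            same = abs(D_here - best_D) <= 1e-15
            closer = np.sum((res.x - center) ** 2) < np.sum((best_x - center) ** 2)
            if better or (same and closer):
                best_D, best_x = D_here, np.asarray(res.x, dtype=float)

    dvec = d_stack(np.array(best_x[0]), np.array(best_x[1]))
    predictions = {
        c.response: float(preds[c.response](np.array(best_x[0]), np.array(best_x[1])))
        for c in criteria
    }
    return OptimumResult(
        factor_values=tuple(float(v) for v in best_x),
        predicted_responses=predictions,
        individual_desirabilities={c.response: float(d) for c, d in zip(criteria, dvec)},
        composite_desirability=float(best_D),
        degenerate=degenerate,
        trace=trace,
    )
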
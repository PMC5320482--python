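"""Derringer desirability functions and multi-response optimization.

Each predicted recovery y is mapped to a partial desirability d in [0, 1]
(0 below the lower anchor L, 1 at or above the target T, a power ramp in
between) and the n responses are combined as the geometric mean
D = (prod d_i)^(1/n).  The extraction settings maximizing D are found by a
dense grid search over the coded region followed by local refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .rsm import QuadraticModel, predict, quadratic_basis

__all__ = [
    "DesirabilitySpec",
    "Optimum",
    "partial_desirability",
    "overall_desirability",
    "auto_range_spec",
    "optimize",
    "desirability_profiles",
]


@dataclass(frozen=True)
class DesirabilitySpec:
    """Larger-is-better desirability: d = ((y-L)/(T-L))^s clipped to [0, 1]."""

    lower: float
    target: float
    s: float = 1.0
    goal: str = "maximize"

    def __post_init__(self) -> None:
        if not self.lower < self.target:
            raise ValueError("lower anchor must be < target")
        if not self.s > 0:
            raise ValueError("exponent s must be > 0")
        if self.goal != "maximize":
            raise ValueError("only goal='maximize' is supported")


@dataclass
class Optimum:
    """Result of the multi-response optimization."""

    coded: np.ndarray
    predictions: dict[str, float]
    d: dict[str, float]
    D: float
    diagnostic: str | None = None
    natural: dict[str, float] = field(default_factory=dict)


def partial_desirability(y, spec: DesirabilitySpec):
    """Map response value(s) to [0, 1] per the one-sided Derringer ramp."""
    y = np.asarray(y, dtype=float)
    frac = np.clip((y - spec.lower) / (spec.target - spec.lower), 0.0, 1.0)
    out = frac**spec.s
    return float(out) if out.ndim == 0 else out


def overall_desirability(d) -> float:
    """Geometric mean of the partial desirabilities."""
    d = np.asarray(d, dtype=float)
    if d.size < 1:
        raise ValueError("need at least one partial desirability")
    if (d < 0).any() or (d > 1).any():
        raise ValueError("partial desirabilities must lie in [0, 1]")
    if (d == 0).any():
        return 0.0
    return float(np.exp(np.mean(np.log(d))))


def _region_grid(f: int, bounds: tuple[float, float], n: int) -> np.ndarray:
    axes = [np.linspace(bounds[0], bounds[1], n)] * f
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([m.ravel() for m in mesh])


def auto_range_spec(
    model: QuadraticModel,
    bounds: tuple[float, float] = (-1.0, 1.0),
    grid_n: int = 41,
    s: float = 1.0,
) -> DesirabilitySpec:
    """Range-scaled anchors: L/T = min/max model prediction over the region.

    This is the software-style scaling under which the region's best point
    attains d = 1 regardless of its absolute recovery.
    """
    pred = predict(model, _region_grid(model.n_factors, bounds, grid_n))
    lo, hi = float(pred.min()), float(pred.max())
    if hi <= lo:  # flat surface: any anchors work, keep d == 1 everywhere
        lo, hi = lo - 1.0, lo + 1.0
    return DesirabilitySpec(lower=lo, target=hi, s=s)


def _overall_on_points(models, specs, pts: np.ndarray) -> np.ndarray:
    """Vectorized D over an array of coded points."""
    B = quadratic_basis(pts)
    logd = np.zeros(len(pts))
    dead = np.zeros(len(pts), dtype=bool)
    for name, model in models.items():
        y = B @ model.coef.to_numpy()
        d = partial_desirability(y, specs[name])
        dead |= d <= 0.0
        with np.errstate(divide="ignore"):
            logd += np.where(d > 0, np.log(np.maximum(d, 1e-300)), 0.0)
    D = np.exp(logd / len(models))
    D[dead] = 0.0
    return D


def optimize(
    models: dict[str, QuadraticModel],
    specs: dict[str, DesirabilitySpec] | str = "auto",
    bounds: tuple[float, float] = (-1.0, 1.0),
    grid_n: int = 21,
) -> Optimum:
    """Maximize overall desirability over the coded region.

    Dense grid search (``grid_n`` per axis) picks the best start — ties
    broken toward the smallest coded norm, then lexicographically — and
    L-BFGS-B refines it.  With ``specs='auto'`` every response gets
    range-scaled anchors from :func:`auto_range_spec`.
    """
    names = list(models)
    f = models[names[0]].n_factors
    if any(m.n_factors != f for m in models.values()):
        raise ValueError("all models must share the same design factors")
    if specs == "auto":
        specs = {n: auto_range_spec(models[n], bounds) for n in names}

    pts = _region_grid(f, bounds, grid_n)
    D = _overall_on_points(models, specs, pts)
    best = D.max()
    diagnostic = None
    if best == 0.0:
        killers = [
            n for n in names
            if partial_desirability(predict(models[n], pts), specs[n]).max() == 0.0
        ]
        diagnostic = (
            "overall desirability is 0 everywhere; responses with d = 0 over "
            f"the whole region: {killers}"
        )
    ties = np.nonzero(D >= best - 1e-12)[0]
    order = sorted(ties, key=lambda i: (np.linalg.norm(pts[i]), tuple(pts[i])))
    x0 = pts[order[0]]

    res = minimize(
        lambda x: -_overall_on_points(models, specs, x[None, :])[0],
        x0,
        method="L-BFGS-B",
        bounds=[bounds] * f,
    )
    x_ref = res.x if res.success and -res.fun >= best else x0
    D_ref = _overall_on_points(models, specs, x_ref[None, :])[0]
    if D_ref < best:  # refinement must never lose to the grid
        x_ref, D_ref = x0, best

    preds = {n: float(predict(models[n], x_ref)) for n in names}
    d = {n: float(partial_desirability(preds[n], specs[n])) for n in names}
    return Optimum(coded=np.asarray(x_ref, dtype=float), predictions=preds,
                   d=d, D=float(D_ref), diagnostic=diagnostic)


def desirability_profiles(
    models: dict[str, QuadraticModel],
    specs: dict[str, DesirabilitySpec],
    optimum: Optimum,
    bounds: tuple[float, float] = (-1.0, 1.0),
    n: int = 101,
) -> pd.DataFrame:
    """1-D sweeps through the optimum: per factor, vary that coordinate over
    the region with the others held at the optimum; report each response's
    prediction and d plus the overall D."""
    names = list(models)
    f = models[names[0]].n_factors
    factor_names = models[names[0]].factor_names
    rows = []
    for j in range(f):
        sweep = np.tile(optimum.coded, (n, 1))
        sweep[:, j] = np.linspace(bounds[0], bounds[1], n)
        D = _overall_on_points(models, specs, sweep)
        block = {
            "factor": factor_names[j],
            "coded_value": sweep[:, j],
            "D": D,
        }
        B = quadratic_basis(sweep)
        for name in names:
            y = B @ models[name].coef.to_numpy()
            block[f"pred_{name}"] = y
            block[f"d_{name}"] = partial_desirability(y, specs[name])
        rows.append(pd.DataFrame(block))
    return pd.concat(rows, ignore_index=True)
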
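"""Particle swarm maximisation over a bounded factor box.

The canonical inertia-weight update: each particle carries a position x and
velocity v inside the box; per iteration

    v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x)
    x <- clip(x + v, bounds)

with r1, r2 fresh uniform(0,1) draws per dimension, velocity zeroed on any
clipped dimension, and personal/global bests updated on strict improvement.
The run stops at the iteration cap or when the global best has improved by
less than a stall tolerance over a stall window.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .ann import EnsembleResult, predict
from .dataset import DesignPoint

__all__ = [
    "SwarmConfig",
    "OptimizationResult",
    "pso_maximize",
    "optimize_extraction",
]


@dataclass(frozen=True)
class SwarmConfig:
    """Particle swarm settings; defaults are standard constriction-equivalent
    constants (inertia 0.729, c1 = c2 = 1.49445)."""

    bounds: tuple[tuple[float, float], ...]
    n_particles: int = 40
    inertia: float = 0.729
    cognitive: float = 1.49445
    social: float = 1.49445
    velocity_cap: float = 0.5  # fraction of each dimension's range
    max_iterations: int = 200
    stall_tolerance: float = 1e-8
    stall_window: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if any(hi <= lo for lo, hi in self.bounds):
            raise ValueError("bounds must be proper intervals")
        if min(self.inertia, self.cognitive, self.social) < 0:
            raise ValueError("coefficients must be >= 0")
        if not 0 < self.velocity_cap <= 1:
            raise ValueError("velocity_cap must be in (0, 1]")


@dataclass(frozen=True)
class OptimizationResult:
    x: tuple[float, ...]  # argmax in raw units
    value: float  # objective at the argmax
    trace: tuple[float, ...]  # global-best value per iteration
    iterations: int
    terminated_by: str  # "max-iter" | "stall"
    snapped: tuple[float, ...] | None = None  # reporting-grid argmax, if asked

    @property
    def point(self) -> DesignPoint:
        """The argmax as a validated extraction design point (requires the
        box to lie in positive factor space)."""
        return DesignPoint(*self.x)

    @property
    def snapped_point(self) -> DesignPoint | None:
        return None if self.snapped is None else DesignPoint(*self.snapped)


def pso_maximize(
    objective: Callable[[np.ndarray], np.ndarray], config: SwarmConfig
) -> OptimizationResult:
    """Maximise a vectorised objective (rows of an (P, d) matrix -> (P,))."""
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    rng_span = hi - lo
    vmax = config.velocity_cap * rng_span
    P, d = config.n_particles, len(config.bounds)

    def evaluate(X: np.ndarray) -> np.ndarray:
        vals = np.asarray(objective(X), dtype=float)
        if vals.shape != (len(X),):
            raise ValueError("objective must return one value per row")
        if not np.all(np.isfinite(vals)):
            bad = X[int(np.argmax(~np.isfinite(vals)))]
            raise ValueError(f"non-finite objective value at point {bad}")
        return vals

    x = lo + rng.uniform(size=(P, d)) * rng_span
    v = rng.uniform(-1.0, 1.0, size=(P, d)) * vmax
    f = evaluate(x)
    pbest_x, pbest_f = x.copy(), f.copy()
    g = int(np.argmax(pbest_f))
    gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])

    trace = [gbest_f]
    terminated_by = "max-iter"
    it = 0
    for it in range(1, config.max_iterations + 1):
        r1 = rng.uniform(size=(P, d))
        r2 = rng.uniform(size=(P, d))
        v = (
            config.inertia * v
            + config.cognitive * r1 * (pbest_x - x)
            + config.social * r2 * (gbest_x - x)
        )
        v = np.clip(v, -vmax, vmax)
        x_new = x + v
        clipped_lo = x_new < lo
        clipped_hi = x_new > hi
        x = np.clip(x_new, lo, hi)
        v[clipped_lo | clipped_hi] = 0.0
        f = evaluate(x)
        improved = f > pbest_f
        pbest_x[improved] = x[improved]
        pbest_f[improved] = f[improved]
        g = int(np.argmax(pbest_f))
        if pbest_f[g] > gbest_f:
            gbest_f = float(pbest_f[g])
            gbest_x = pbest_x[g].copy()
        trace.append(gbest_f)
        w = config.stall_window
        if it >= w and trace[-1] - trace[-1 - w] < config.stall_tolerance:
            terminated_by = "stall"
            break
    return OptimizationResult(
        x=tuple(float(v) for v in gbest_x),
        value=gbest_f,
        trace=tuple(trace),
        iterations=it,
        terminated_by=terminated_by,
    )


def optimize_extraction(
    ensemble: EnsembleResult,
    bounds: tuple[tuple[float, float], ...] | None = None,
    config: SwarmConfig | None = None,
    mode: str = "mean",
    snap: bool = False,
) -> OptimizationResult:
    """Locate the extraction conditions maximising the predicted TPC yield.

    The objective is the ensemble prediction (mean mode by default, which
    smooths single-network interpolation artifacts; champion mode selectable)
    over the factor box. Bounds default to the ensemble's training ranges.
    With ``snap`` the argmax is additionally rounded to whole watts, minutes
    and solvent parts for reporting.
    """
    scaler = ensemble.scaler
    if bounds is None:
        bounds = tuple(
            (float(scaler.mins[i]), float(scaler.maxs[i])) for i in range(3)
        )
    else:
        bounds = tuple((float(lo), float(hi)) for lo, hi in bounds)
    if config is None:
        config = SwarmConfig(bounds=bounds)
    elif config.bounds != tuple(bounds):
        config = SwarmConfig(**{**config.__dict__, "bounds": tuple(bounds)})

    def objective(X: np.ndarray) -> np.ndarray:
        return predict(ensemble, X, mode=mode)

    result = pso_maximize(objective, config)
    if snap:
        # reporting grid: whole watts, minutes and solvent parts
        snapped = tuple(float(round(v)) for v in result.x)
        return dataclasses.replace(result, snapped=snapped)
    return result
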
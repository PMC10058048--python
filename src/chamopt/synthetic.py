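"""Synthetic response surfaces for recovery testing.

A full quadratic polynomial in the three extraction factors (linear,
pure-quadratic and pairwise-interaction terms) with additive i.i.d. Gaussian
noise stands in for the unknown true yield surface. Because the surface and
its box-constrained argmax are known analytically, every downstream stage —
network fitting, importance attribution and swarm optimization — can be tested
by parameter/argmax recovery without any laboratory data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .dataset import Dataset, DesignPoint, ExtractionRecord

__all__ = [
    "SurfaceSpec",
    "evaluate_surface",
    "generate",
    "analytic_argmax",
    "full_factorial",
    "chamomile_like_surface",
]


@dataclass(frozen=True)
class SurfaceSpec:
    """A quadratic 3-factor response surface with Gaussian observation noise.

    The noise-free value at x = (x1, x2, x3) is

        y(x) = c0 + sum_i b_i x_i + sum_i a_i x_i^2
             + q12 x1 x2 + q13 x1 x3 + q23 x2 x3

    with ``noise_sd`` the standard deviation (response units) of the additive
    Gaussian error and ``bounds`` the factor box the surface is defined on.
    """

    intercept: float
    linear: tuple[float, float, float]
    quadratic: tuple[float, float, float]
    interactions: tuple[float, float, float]  # (q12, q13, q23)
    noise_sd: float
    bounds: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.bounds) != 3 or any(hi <= lo for lo, hi in self.bounds):
            raise ValueError("bounds must be three proper intervals")

    # -- quadratic-form pieces -------------------------------------------
    @property
    def hessian(self) -> np.ndarray:
        a1, a2, a3 = self.quadratic
        q12, q13, q23 = self.interactions
        return np.array(
            [[2 * a1, q12, q13], [q12, 2 * a2, q23], [q13, q23, 2 * a3]]
        )

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "linear": list(self.linear),
            "quadratic": list(self.quadratic),
            "interactions": list(self.interactions),
            "noise_sd": self.noise_sd,
            "bounds": [list(b) for b in self.bounds],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SurfaceSpec":
        return cls(
            intercept=float(d["intercept"]),
            linear=tuple(float(v) for v in d["linear"]),
            quadratic=tuple(float(v) for v in d["quadratic"]),
            interactions=tuple(float(v) for v in d["interactions"]),
            noise_sd=float(d["noise_sd"]),
            bounds=tuple(tuple(float(v) for v in b) for b in d["bounds"]),
        )


def _check_in_bounds(spec: SurfaceSpec, X: np.ndarray) -> None:
    lo = np.array([b[0] for b in spec.bounds])
    hi = np.array([b[1] for b in spec.bounds])
    if np.any(X < lo) or np.any(X > hi):
        bad = np.argwhere((X < lo) | (X > hi))[0]
        raise ValueError(f"design point outside surface bounds at row {bad[0]}")


def _poly(spec: SurfaceSpec, X: np.ndarray) -> np.ndarray:
    x1, x2, x3 = X[:, 0], X[:, 1], X[:, 2]
    b1, b2, b3 = spec.linear
    a1, a2, a3 = spec.quadratic
    q12, q13, q23 = spec.interactions
    return (
        spec.intercept
        + b1 * x1 + b2 * x2 + b3 * x3
        + a1 * x1**2 + a2 * x2**2 + a3 * x3**2
        + q12 * x1 * x2 + q13 * x1 * x3 + q23 * x2 * x3
    )


def evaluate_surface(spec: SurfaceSpec, point: DesignPoint | np.ndarray) -> float | np.ndarray:
    """Noise-free surface value at one point or at each row of a matrix."""
    X = point.as_array()[None, :] if isinstance(point, DesignPoint) else np.atleast_2d(
        np.asarray(point, dtype=float)
    )
    _check_in_bounds(spec, X)
    vals = _poly(spec, X)
    return float(vals[0]) if (isinstance(point, DesignPoint) or np.asarray(point).ndim == 1) else vals


def generate(spec: SurfaceSpec, design: Sequence[DesignPoint], seed: int) -> Dataset:
    """Sample the surface at ``design`` with seeded Gaussian noise.

    tpc = surface value + N(0, noise_sd^2), independent across rows. With
    ``noise_sd == 0`` the generated responses equal the surface exactly.
    """
    X = np.array([p.as_array() for p in design])
    _check_in_bounds(spec, X)
    rng = np.random.default_rng(seed)
    y = _poly(spec, X) + rng.normal(0.0, spec.noise_sd, size=len(design))
    records = tuple(
        ExtractionRecord(point=p, tpc=float(v)) for p, v in zip(design, y)
    )
    return Dataset(records=records, name=f"synthetic(seed={seed})")


def full_factorial(levels: Sequence[Sequence[float]]) -> list[DesignPoint]:
    """All combinations of the given per-factor levels, outer-product order."""
    pts = []
    for p in levels[0]:
        for t in levels[1]:
            for s in levels[2]:
                pts.append(DesignPoint(power_W=p, time_min=t, solvent_parts=s))
    return pts


def analytic_argmax(
    spec: SurfaceSpec, grid_resolution: int = 201
) -> tuple[np.ndarray, float]:
    """Exact maximizing coordinates (and value) of the noise-free surface
    over its bounds.

    When the Hessian is negative definite and the stationary point (the
    solution of H x = -b) lies inside the box, that point is the maximizer.
    Otherwise the best point of a ``grid_resolution``-per-axis dense grid is
    refined by bounded local polish (L-BFGS-B on the negated surface).
    """
    lo = np.array([b[0] for b in spec.bounds])
    hi = np.array([b[1] for b in spec.bounds])
    H = spec.hessian
    b = np.array(spec.linear)
    eig = np.linalg.eigvalsh(H)
    if np.all(eig < 0):
        x_star = np.linalg.solve(H, -b)
        if np.all(x_star >= lo) and np.all(x_star <= hi):
            return x_star, float(_poly(spec, x_star[None, :])[0])
    # grid fallback: dense scan, then local polish from the best cell
    axes = [np.linspace(l, h, grid_resolution) for l, h in zip(lo, hi)]
    G1, G2, G3 = np.meshgrid(*axes, indexing="ij")
    X = np.column_stack([G1.ravel(), G2.ravel(), G3.ravel()])
    vals = _poly(spec, X)
    x0 = X[np.argmax(vals)]
    res = minimize(
        lambda x: -_poly(spec, x[None, :])[0],
        x0,
        method="L-BFGS-B",
        bounds=list(zip(lo, hi)),
    )
    x_best = res.x if -res.fun >= vals.max() else x0
    return np.asarray(x_best), float(_poly(spec, x_best[None, :])[0])


def chamomile_like_surface(noise_sd: float = 1.5) -> SurfaceSpec:
    """A realistic preset surface for the chamomile extraction factor box.

    Coefficients are frozen constants obtained once by ordinary least squares
    of the full quadratic on the packaged 27-run dataset; they are artifact
    constants describing a plausible yield surface (raw units: W, min, parts,
    mg/g), not measured claims. The default noise SD of 1.5 mg/g is a
    replicate-scale error of roughly 3% of the mean yield.
    """
    return SurfaceSpec(
        intercept=-2.6962037037034974,
        linear=(-0.05839305555554709, 0.6998611111110721, 1.4839861111112154),
        quadratic=(5.584027777780657e-05, -0.0005222222222183801, -0.006488888888888287),
        interactions=(0.00015083333333306212, -0.00018041666666695946, -0.009945833333335137),
        noise_sd=noise_sd,
        bounds=((400.0, 800.0), (20.0, 40.0), (40.0, 80.0)),
    )
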
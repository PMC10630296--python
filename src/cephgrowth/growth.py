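"""Double-logistic growth curve: size, velocity, and growth milestones.

The model describes a linear skeletal trait (an inter-landmark distance in
mm) as the sum of two logistic growth phases, prepubertal and adolescent::

    y(age) = a1 / (1 + exp(-b1 (age - c1))) + (f - a1) / (1 + exp(-b2 (age - c2)))

``f`` is the asymptotic trait size at growth cessation, ``a1`` the asymptote
of the prepubertal phase, ``b1``/``b2`` the phase growth-rate parameters
(1/year), and ``c1``/``c2`` the ages at maximal phase growth rate (years).
With ``b1, b2 > 0`` and ``f > a1`` the curve increases monotonically; the
first derivative is the growth rate (mm/year), whose maximum over an age
window defines the peak growth velocity (PGV) and the age at which it occurs
(aPGV) -- the milestones orthodontic treatment timing is keyed to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit

__all__ = ["GrowthParams", "Milestones", "double_logistic", "growth_velocity", "find_milestones"]


@dataclass(frozen=True)
class GrowthParams:
    """Population parameters of the double-logistic growth equation.

    Attributes
    ----------
    f : float
        Asymptotic trait size at growth cessation (mm).
    a1 : float
        Prepubertal-phase asymptote (mm).
    b1, b2 : float
        Prepubertal / adolescent growth-rate parameters (1/year); must be
        positive so that the curve is monotone.
    c1, c2 : float
        Ages at maximal prepubertal / adolescent growth rate (years).
    """

    f: float
    a1: float
    b1: float
    c1: float
    b2: float
    c2: float

    def __post_init__(self) -> None:
        for name in self.param_names():
            object.__setattr__(self, name, float(getattr(self, name)))
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite growth parameter in {self}")
        if self.b1 <= 0 or self.b2 <= 0:
            raise ValueError(f"rate parameters must be positive: b1={self.b1}, b2={self.b2}")
        if self.f <= 0 or self.a1 < 0:
            raise ValueError(f"size parameters must be positive: f={self.f}, a1={self.a1}")
        if self.f < self.a1:
            # Not forbidden, but the monotonicity guarantee no longer holds.
            warnings.warn(
                f"f={self.f} < a1={self.a1}: adolescent phase is negative; "
                "the growth curve is not guaranteed monotone",
                stacklevel=3,
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.f, self.a1, self.b1, self.c1, self.b2, self.c2], dtype=float)

    @classmethod
    def param_names(cls) -> tuple[str, ...]:
        return tuple(fld.name for fld in fields(cls))

    @classmethod
    def from_array(cls, values: np.ndarray) -> "GrowthParams":
        f, a1, b1, c1, b2, c2 = (float(v) for v in values)
        return cls(f=f, a1=a1, b1=b1, c1=c1, b2=b2, c2=c2)


@dataclass(frozen=True)
class Milestones:
    """Growth milestones extracted from a fitted curve.

    ``pgv`` is the peak growth velocity (mm/year) over the evaluated age
    window, ``apgv`` the age at which it occurs (years), ``asymptote`` the
    trait size at growth cessation (mm), and ``phase`` records whether the
    prepubertal or the adolescent logistic contributes more velocity at the
    peak.
    """

    pgv: float
    apgv: float
    asymptote: float
    phase: str  # "prepubertal" | "adolescent"


def _check_ages(age) -> np.ndarray:
    arr = np.asarray(age, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("ages must be finite")
    return arr


def double_logistic(age, params: GrowthParams) -> np.ndarray:
    """Evaluate the double-logistic growth curve (mm) at ``age`` (years).

    Vectorized over ``age``; scalar input returns a 0-d array convertible
    with ``float()``.
    """
    a = _check_ages(age)
    s1 = expit(params.b1 * (a - params.c1))
    s2 = expit(params.b2 * (a - params.c2))
    return params.a1 * s1 + (params.f - params.a1) * s2


def growth_velocity(age, params: GrowthParams) -> np.ndarray:
    """Closed-form first derivative of the growth curve (mm/year).

    d y / d age = a1 b1 S1 (1 - S1) + (f - a1) b2 S2 (1 - S2), with S_k the
    two logistic terms. Non-negative everywhere when f >= a1.
    """
    a = _check_ages(age)
    s1 = expit(params.b1 * (a - params.c1))
    s2 = expit(params.b2 * (a - params.c2))
    return params.a1 * params.b1 * s1 * (1.0 - s1) + (params.f - params.a1) * params.b2 * s2 * (1.0 - s2)


def find_milestones(
    params: GrowthParams,
    age_window: tuple[float, float],
    grid_step: float = 0.01,
) -> Milestones:
    """Locate the velocity maximum on ``age_window`` = (lo, hi).

    A dense grid scan (step <= ``grid_step`` years) finds the approximate
    argmax; bounded scalar minimization of the negative velocity within one
    grid step on either side refines it. Ties on the grid break toward the
    older age. The window should start after the prepubertal peak region
    when the adolescent spurt is the milestone of interest.
    """
    lo, hi = float(age_window[0]), float(age_window[1])
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo >= hi:
        raise ValueError(f"invalid age window [{lo}, {hi}]")
    n = max(int(np.ceil((hi - lo) / grid_step)) + 1, 2)
    grid = np.linspace(lo, hi, n)
    vel = growth_velocity(grid, params)
    # argmax with ties toward the older age
    best = len(vel) - 1 - int(np.argmax(vel[::-1]))
    a_lo = grid[max(best - 1, 0)]
    a_hi = grid[min(best + 1, len(grid) - 1)]
    if a_hi > a_lo:
        res = minimize_scalar(
            lambda a: -float(growth_velocity(a, params)),
            bounds=(a_lo, a_hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        apgv, pgv = float(res.x), -float(res.fun)
        if pgv < vel[best]:  # refinement must never lose to the grid
            apgv, pgv = float(grid[best]), float(vel[best])
    else:
        apgv, pgv = float(grid[best]), float(vel[best])
    s1 = expit(params.b1 * (apgv - params.c1))
    s2 = expit(params.b2 * (apgv - params.c2))
    v1 = params.a1 * params.b1 * s1 * (1.0 - s1)
    v2 = (params.f - params.a1) * params.b2 * s2 * (1.0 - s2)
    phase = "adolescent" if v2 >= v1 else "prepubertal"
    return Milestones(pgv=pgv, apgv=apgv, asymptote=params.f, phase=phase)
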
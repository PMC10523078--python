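"""Closed-form skeleton of the periodically forced Rosenzweig–MacArthur model.

The model couples a logistically growing resource R to a consumer C with a
saturating (Holling type II) functional response::

    dR/dt = R * ( r * (1 - R / K(t)) - a * C / (b + R) )
    dC/dt = C * ( e * a * R / (b + R) - d )

Environmental forcing enters through the carrying capacity (productivity),

    K(t) = K_mean + A * sin(2 * pi * p * t),

so one forcing cycle lasts ``1/p`` time units.  Everything in this module is
analytic: isoclines, the interior equilibrium, the Jacobian evaluated there,
its dominant eigenvalue, and the Hopf bifurcation point ``K_Hopf`` where the
equilibrium loses stability and a limit cycle is born (the classic paradox of
enrichment as productivity rises).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import (
    AmplitudeError,
    NoCoexistenceError,
    ParameterError,
)

__all__ = [
    "ModelParams",
    "ForcingSpec",
    "State",
    "Equilibrium",
    "forcing_value",
    "carrying_capacity",
    "vector_field",
    "rhs",
    "resource_isocline",
    "consumer_isocline_R",
    "interior_equilibrium",
    "jacobian",
    "lambda_max_re",
    "lambda_max",
    "k_hopf",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class ModelParams:
    """The six biological rates of the deterministic skeleton.

    Parameters
    ----------
    r
        Intrinsic growth rate of the resource (per time).
    K_mean
        Average carrying capacity of the resource (density).
    a
        Consumer attack rate (per time).
    e
        Conversion efficiency of consumed resource into consumers
        (dimensionless, 0–1).
    b
        Half-saturation constant of the functional response (density).
    d
        Consumer natural mortality (per time).

    Coexistence requires ``a * e > d``: without it the consumer cannot
    sustain itself at any resource density and there is no positive interior
    equilibrium, so such parameter sets are rejected outright.
    """

    r: float
    K_mean: float
    a: float
    e: float
    b: float
    d: float

    def __post_init__(self) -> None:
        for name in ("r", "K_mean", "a", "e", "b", "d"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0.0):
                raise ParameterError(f"{name} must be strictly positive, got {v!r}")
        if not 0.0 < self.e <= 1.0:
            raise ParameterError(f"conversion efficiency e must be in (0, 1], got {self.e}")
        if self.a * self.e <= self.d:
            raise ParameterError(
                "degenerate parameters: a*e must exceed d for a positive interior "
                f"equilibrium (a*e={self.a * self.e:.6g}, d={self.d:.6g})"
            )

    def with_K(self, K: float) -> "ModelParams":
        """A copy of these parameters with a different mean carrying capacity."""
        return replace(self, K_mean=K)


@dataclass(frozen=True)
class ForcingSpec:
    """Sinusoidal productivity forcing: amplitude ``A`` and speed ``p``.

    The forcing period (duration of one K cycle) is ``1/p`` time units.
    ``A = 0`` recovers the unforced, autonomous model.
    """

    A: float
    p: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.A) and self.A >= 0.0):
            raise ParameterError(f"forcing amplitude A must be >= 0, got {self.A}")
        if not (math.isfinite(self.p) and self.p > 0.0):
            raise ParameterError(f"forcing speed p must be > 0, got {self.p}")

    @property
    def period(self) -> float:
        """Duration of one forcing cycle, ``1/p``."""
        return 1.0 / self.p

    @classmethod
    def unforced(cls, p: float = 1.0) -> "ForcingSpec":
        return cls(A=0.0, p=p)


@dataclass(frozen=True)
class State:
    """Instantaneous densities of resource R and consumer C."""

    R: float
    C: float

    def __post_init__(self) -> None:
        if self.R < 0.0 or self.C < 0.0:
            raise ParameterError(f"densities must be non-negative, got R={self.R}, C={self.C}")


@dataclass(frozen=True)
class Equilibrium:
    """Interior equilibrium at a fixed carrying capacity ``K``.

    ``R_star`` depends only on the biological rates, never on K; varying K
    moves the equilibrium only in the consumer direction.  ``excitable`` is
    True when the eigenvalues are complex, i.e. perturbations return (or
    depart, above the Hopf point) through overshoot oscillations.
    """

    R_star: float
    C_star: float
    K: float
    lambda_re: float
    lambda_im: float
    excitable: bool


# ---------------------------------------------------------------------------
# forcing and vector field
# ---------------------------------------------------------------------------


def forcing_value(f: ForcingSpec, t: float) -> float:
    """Productivity offset ``A * sin(2*pi*p*t)`` at time ``t``; lies in [-A, A]."""
    return f.A * math.sin(f.p * TWO_PI * t)


def carrying_capacity(m: ModelParams, f: ForcingSpec, t: float) -> float:
    """Instantaneous carrying capacity ``K_mean + A*sin(2*pi*p*t)``.

    Raises
    ------
    AmplitudeError
        If ``A >= K_mean`` — the trough of the cycle would make productivity
        non-positive, which is biologically meaningless.
    """
    if f.A >= m.K_mean:
        raise AmplitudeError(
            f"forcing amplitude A={f.A} must stay below K_mean={m.K_mean}; "
            "carrying capacity would become non-positive during the cycle"
        )
    return m.K_mean + forcing_value(f, t)


def vector_field(m: ModelParams, f: ForcingSpec, s: State, t: float = 0.0) -> tuple[float, float]:
    """Time derivatives ``(dR/dt, dC/dt)`` of the forced system at state ``s``."""
    K = carrying_capacity(m, f, t)
    R, C = s.R, s.C
    dR = R * (m.r * (1.0 - R / K) - m.a * C / (m.b + R))
    dC = C * (m.e * m.a * R / (m.b + R) - m.d)
    return dR, dC


def rhs(m: ModelParams, f: ForcingSpec):
    """Right-hand side ``g(t, y)`` closure for ODE solvers (y = [R, C]).

    Validates the amplitude once up front so the per-step path is pure
    arithmetic.
    """
    if f.A >= m.K_mean:
        raise AmplitudeError(
            f"forcing amplitude A={f.A} must stay below K_mean={m.K_mean}"
        )
    r, a, e, b, d = m.r, m.a, m.e, m.b, m.d
    K_mean, A, w = m.K_mean, f.A, f.p * TWO_PI

    def g(t, y):
        R, C = y
        K = K_mean + A * math.sin(w * t)
        denom = b + R
        return (
            R * (r * (1.0 - R / K) - a * C / denom),
            C * (e * a * R / denom - d),
        )

    return g


# ---------------------------------------------------------------------------
# isoclines and equilibrium
# ---------------------------------------------------------------------------


def resource_isocline(m: ModelParams, K: float, R):
    """Consumer density on the resource nullcline (dR/dt = 0) at density ``R``.

    ``C = -r (b + R)(R - K) / (a K)``: a hump with apex at ``R = (K - b)/2``,
    intercepts ``C = r b / a`` at R → 0 and ``C = 0`` at ``R = K`` (the axial
    equilibrium).  Accepts scalars or arrays in ``R``.
    """
    if K <= 0.0:
        raise ParameterError(f"carrying capacity K must be positive, got {K}")
    R = np.asarray(R, dtype=float) if not np.isscalar(R) else R
    return -m.r * (m.b + R) * (R - K) / (m.a * K)


def consumer_isocline_R(m: ModelParams) -> float:
    """Resource density on the (vertical) consumer nullcline: ``R* = d b / (a e - d)``.

    Independent of K — this is also the resource coordinate of the interior
    equilibrium.  Degenerate parameter sets (``a e <= d``) are rejected at
    :class:`ModelParams` construction.
    """
    return m.d * m.b / (m.a * m.e - m.d)


def _trace_det(m: ModelParams, K: float) -> tuple[float, float]:
    """Trace and determinant of the Jacobian at the interior equilibrium."""
    r, a, e, b, d = m.r, m.a, m.e, m.b, m.d
    ae = a * e
    tr = r * (a * d * e * (K - b) - d * d * (b + K)) / (ae * K * (ae - d))
    det = (d / e) * r * (ae * K - b * d - d * K) / (a * K)
    return tr, det


def interior_equilibrium(m: ModelParams, K: float | None = None) -> Equilibrium:
    """Coexistence equilibrium (R*, C*) at carrying capacity ``K``.

    ``R* = b d / (a e - d)`` is K-invariant; ``C*`` is the resource isocline
    evaluated at R*, so increasing K moves the equilibrium vertically in the
    phaseplane.  The dominant eigenvalue of the Jacobian there is attached,
    with ``excitable=True`` when the pair is complex.

    Raises
    ------
    NoCoexistenceError
        If ``K <= R*`` (the consumer nullcline lies outside the resource
        hump, so C* would be non-positive).
    """
    if K is None:
        K = m.K_mean
    R_star = consumer_isocline_R(m)
    if K <= R_star:
        raise NoCoexistenceError(
            f"no coexistence: K={K:.6g} must exceed R*={R_star:.6g}"
        )
    C_star = float(resource_isocline(m, K, R_star))
    lam_re, lam_im = lambda_max(m, K)
    return Equilibrium(
        R_star=R_star,
        C_star=C_star,
        K=K,
        lambda_re=lam_re,
        lambda_im=lam_im,
        excitable=lam_im != 0.0,
    )


def jacobian(m: ModelParams, K: float) -> np.ndarray:
    """Jacobian of the unforced vector field at the interior equilibrium.

    Closed form::

        [[ tr(J),  -d/e ],
         [ J21,     0   ]]     with J21 = r (a e K - b d - d K) / (a K)

    The lower-right entry vanishes identically because the consumer nullcline
    pins ``e a R*/(b + R*) = d``.
    """
    R_star = consumer_isocline_R(m)
    if K <= R_star:
        raise NoCoexistenceError(
            f"no coexistence: K={K:.6g} must exceed R*={R_star:.6g}"
        )
    tr, _ = _trace_det(m, K)
    j21 = m.r * (m.a * m.e * K - m.b * m.d - m.d * K) / (m.a * K)
    return np.array([[tr, -m.d / m.e], [j21, 0.0]])


def lambda_max(m: ModelParams, K: float) -> tuple[float, float]:
    """(real, imaginary) parts of the dominant eigenvalue at the equilibrium.

    When the discriminant of the characteristic polynomial is negative the
    real part is ``tr(J)/2`` — the closed form used throughout the local
    stability analysis — and the imaginary part is ``sqrt(-disc)/2``.  When
    the eigenvalues are real (very low K, below the bottom of the eigenvalue
    "checkmark") the larger root is returned and the imaginary part is 0; the
    two branches join continuously.
    """
    R_star = consumer_isocline_R(m)
    if K <= R_star:
        raise NoCoexistenceError(
            f"no coexistence: K={K:.6g} must exceed R*={R_star:.6g}"
        )
    tr, det = _trace_det(m, K)
    disc = tr * tr - 4.0 * det
    if disc < 0.0:
        return tr / 2.0, math.sqrt(-disc) / 2.0
    return (tr + math.sqrt(disc)) / 2.0, 0.0


def lambda_max_re(m: ModelParams, K: float) -> float:
    """Real part of the dominant eigenvalue at the interior equilibrium."""
    return lambda_max(m, K)[0]


def k_hopf(m: ModelParams) -> float:
    """Hopf bifurcation point ``K_Hopf = b (d + a e) / (a e - d)``.

    The equilibrium is stable for ``R* < K < K_Hopf`` and sheds a stable
    limit cycle beyond it; the closed form follows from setting the real part
    of the dominant eigenvalue to zero.  Independent of r, linear in b.
    """
    return m.b * (m.d + m.a * m.e) / (m.a * m.e - m.d)


def eigenvalue_checkmark_bottom(m: ModelParams) -> float:
    """K at the bottom of the eigenvalue 'checkmark' (most stable point).

    Below this K the eigenvalues are real (monotonic approach to
    equilibrium); above it they are complex and the dynamics are excitable.
    Located by bisection on the discriminant between R* and K_Hopf.
    """
    from scipy.optimize import brentq

    R_star = consumer_isocline_R(m)

    def disc(K: float) -> float:
        tr, det = _trace_det(m, K)
        return tr * tr - 4.0 * det

    lo = R_star * (1.0 + 1e-9)
    hi = k_hopf(m)
    # disc > 0 just above R* (det -> 0), disc < 0 at K_Hopf (tr = 0, det > 0)
    return float(brentq(disc, lo, hi, xtol=1e-12, rtol=1e-14))
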
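"""Numerical integration of the forced system and the sampling protocol.

The asymptotic-state protocol mirrors the study design: integrate well past
the transient (longer transients for slower forcing, 5 000 time units for
p >= 1 up to 90 000 at the slowest speeds), then sample the terminal window
of ``max(4/p, 1000)`` time units — four full forcing periods or 1000 time
units, whichever is larger.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import NoCoexistenceError, SolverError, WindowError
from .model import ForcingSpec, ModelParams, State, interior_equilibrium, rhs

__all__ = [
    "SimProtocol",
    "Trajectory",
    "sampling_window_length",
    "default_protocol",
    "default_initial_conditions",
    "integrate",
    "asymptotic_window",
]

logger = logging.getLogger(__name__)

#: transient of 5 000 time units for p >= ~1, growing like 9/p for slower
#: forcing, capped at 90 000 at the slow end of the studied range (p ~ 1e-4).
_TRANSIENT_MIN = 5_000.0
_TRANSIENT_MAX = 90_000.0
_T_TOTAL_MIN = 50_000.0


@dataclass(frozen=True)
class SimProtocol:
    """Integration and sampling settings for one run.

    ``sample_dt`` is the spacing of the dense output grid; CV statistics are
    computed on this even grid, never on the solver's internal (adaptively
    clustered) steps.
    """

    t_total: float
    t_transient: float
    rel_tol: float = 1e-9
    abs_tol: float = 1e-11
    max_step: float = math.inf
    sample_dt: float = 0.05
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if not self.t_transient < self.t_total:
            raise WindowError(
                f"t_transient={self.t_transient} must be smaller than t_total={self.t_total}"
            )
        if self.rel_tol <= 0 or self.abs_tol <= 0 or self.sample_dt <= 0:
            raise WindowError("tolerances and sample_dt must be positive")


@dataclass
class Trajectory:
    """Densely sampled (t, R, C) solution with full provenance of the run."""

    times: np.ndarray
    R: np.ndarray
    C: np.ndarray
    params: ModelParams
    forcing: ForcingSpec
    protocol: SimProtocol
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.R) == len(self.C)):
            raise ValueError("times, R and C must have equal lengths")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t": self.times, "R": self.R, "C": self.C})

    def slice(self, t_start: float, t_end: float) -> "Trajectory":
        """Sub-trajectory with t_start <= t <= t_end (absolute times kept)."""
        mask = (self.times >= t_start) & (self.times <= t_end)
        return dataclasses.replace(
            self, times=self.times[mask], R=self.R[mask], C=self.C[mask]
        )

    def provenance(self) -> dict:
        from . import __version__

        return {
            "params": dataclasses.asdict(self.params),
            "forcing": dataclasses.asdict(self.forcing),
            "protocol": dataclasses.asdict(self.protocol),
            "solver_stats": self.stats,
            "crforce_version": __version__,
        }

    def write_csv(self, path) -> None:
        """Write t,R,C as CSV plus a ``<path>.provenance.json`` sidecar."""
        import pandas as pd  # noqa: F401

        self.to_frame().to_csv(path, index=False, float_format="%.12g")
        sidecar = f"{path}.provenance.json"
        with open(sidecar, "w") as fh:
            json.dump(self.provenance(), fh, indent=2, default=float)


def sampling_window_length(f: ForcingSpec) -> float:
    """Length of the terminal CV window: ``max(4/p, 1000)`` time units."""
    return max(4.0 / f.p, 1000.0)


def default_protocol(f: ForcingSpec) -> SimProtocol:
    """Study-fidelity protocol for forcing speed ``p``.

    Transients grow with the forcing period (slow cycles take far longer to
    reach the asymptotic attractor); the total run is at least 50 000 time
    units and always covers transient + sampling window.  The output grid
    ``sample_dt = min(0.01/p, 0.05)`` resolves both the intrinsic cycles and
    fast forcing envelopes.
    """
    t_transient = min(_TRANSIENT_MAX, max(_TRANSIENT_MIN, 9.0 / f.p))
    t_total = max(_T_TOTAL_MIN, t_transient + sampling_window_length(f))
    return SimProtocol(
        t_total=t_total,
        t_transient=t_transient,
        sample_dt=min(0.01 / f.p, 0.05),
    )


def default_initial_conditions(m: ModelParams, perturbation: float = 0.01) -> State:
    """Interior equilibrium at K_mean, perturbed multiplicatively by +1%.

    A deterministic nudge off the (possibly unstable) equilibrium: no random
    seeds anywhere, yet trajectories depart toward the attractor.
    """
    eq = interior_equilibrium(m, m.K_mean)
    return State(R=eq.R_star * (1.0 + perturbation), C=eq.C_star * (1.0 + perturbation))


def integrate(
    m: ModelParams,
    f: ForcingSpec,
    s0: State | None = None,
    proto: SimProtocol | None = None,
) -> Trajectory:
    """Integrate the forced system over ``[0, t_total]``.

    Adaptive integration with automatic stiffness switching (LSODA by
    default; any ``scipy.integrate.solve_ivp`` method name is accepted).
    Densities that dip below zero by less than ``10 * abs_tol`` — harmless
    solver ripple near an excursion toward the axes — are clipped to zero
    with a warning; anything lower is treated as an integration failure.
    """
    if proto is None:
        proto = default_protocol(f)
    if s0 is None:
        s0 = default_initial_conditions(m)

    g = rhs(m, f)
    # never let the solver stride over a forcing oscillation
    max_step = proto.max_step
    if f.A > 0.0:
        max_step = min(max_step, 0.25 / f.p)
    n = int(math.floor(proto.t_total / proto.sample_dt))
    t_eval = np.linspace(0.0, n * proto.sample_dt, n + 1)
    if t_eval[-1] < proto.t_total:
        t_eval = np.append(t_eval, proto.t_total)

    sol = solve_ivp(
        g,
        (0.0, proto.t_total),
        [s0.R, s0.C],
        method=proto.method,
        rtol=proto.rel_tol,
        atol=proto.abs_tol,
        max_step=max_step,
        t_eval=t_eval,
    )
    if not sol.success:
        t_fail = float(sol.t[-1]) if len(sol.t) else 0.0
        raise SolverError(f"integration failed at t={t_fail:.6g}: {sol.message}", t_fail)

    R, C = sol.y
    floor = -10.0 * proto.abs_tol
    worst = min(R.min(initial=0.0), C.min(initial=0.0))
    if worst < floor:
        raise SolverError(
            f"negative densities beyond tolerance (min={worst:.3g} < {floor:.3g})"
        )
    if worst < 0.0:
        warnings.warn(
            f"clipped densities in [{worst:.3g}, 0) to zero (solver ripple)",
            stacklevel=2,
        )
        R = np.clip(R, 0.0, None)
        C = np.clip(C, 0.0, None)

    stats = {"nfev": int(sol.nfev), "njev": int(sol.njev), "nlu": int(sol.nlu)}
    logger.debug("integrate: t_total=%g nfev=%d", proto.t_total, sol.nfev)
    return Trajectory(
        times=sol.t, R=R, C=C, params=m, forcing=f, protocol=proto, stats=stats
    )


def asymptotic_window(traj: Trajectory, f: ForcingSpec | None = None) -> Trajectory:
    """Terminal slice of length ``max(4/p, 1000)`` used for CV statistics.

    Raises
    ------
    WindowError
        If the window would reach back into the transient (or past t=0).
    """
    if f is None:
        f = traj.forcing
    window = sampling_window_length(f)
    t_end = float(traj.times[-1])
    t_start = t_end - window
    if t_start < traj.protocol.t_transient:
        raise WindowError(
            f"sampling window of {window:g} time units reaches into the transient "
            f"(run ends at {t_end:g}, transient {traj.protocol.t_transient:g})"
        )
    return traj.slice(t_start, t_end)
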
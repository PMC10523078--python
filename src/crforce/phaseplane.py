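"""Phaseplane geometry exports: isoclines, vector fields, reference attractors.

The phaseplane is the natural place to read the forced dynamics: the consumer
isocline is a K-invariant vertical line at R*, the resource isocline is a
hump whose C = 0 intercept sits exactly at R = K, and varying K slides the
interior equilibrium purely vertically.  A portrait bundles these curves with
the deterministic attractors at the trough, mean and crest of the K cycle
(point below the Hopf bifurcation, limit-cycle polyline above it) and the
asymptotic window of a forced trajectory overlaid on top.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .exceptions import NoCoexistenceError
from .model import (
    ForcingSpec,
    ModelParams,
    State,
    consumer_isocline_R,
    interior_equilibrium,
    k_hopf,
    resource_isocline,
    vector_field,
)
from .simulate import Trajectory, asymptotic_window

__all__ = ["PhasePortrait", "build_portrait", "vector_field_grid", "render_portrait"]

ATTRACTOR_POINTS = 500  # resampling resolution of limit-cycle polylines


@dataclass
class PhasePortrait:
    """Curves and overlays for one phaseplane figure."""

    R_grid: np.ndarray
    resource_isocline_C: np.ndarray
    consumer_isocline_R: float
    arrow_positions: np.ndarray  # (n, 2)
    arrow_directions: np.ndarray  # (n, 2), unit vectors
    arrow_magnitudes: np.ndarray  # (n,)
    attractors: dict = field(default_factory=dict)  # K -> (N, 2) polyline
    overlay: np.ndarray | None = None  # (N, 2) forced trajectory window
    bounds: tuple = ((0.0, 1.0), (0.0, 1.0))

    def write_csv_bundle(self, directory) -> None:
        """One CSV per curve: isoclines, arrows, attractors, overlay."""
        import pandas as pd

        os.makedirs(directory, exist_ok=True)
        pd.DataFrame(
            {"R": self.R_grid, "C": self.resource_isocline_C}
        ).to_csv(os.path.join(directory, "resource_isocline.csv"), index=False)
        pd.DataFrame({"R": [self.consumer_isocline_R]}).to_csv(
            os.path.join(directory, "consumer_isocline.csv"), index=False
        )
        pd.DataFrame(
            {
                "R": self.arrow_positions[:, 0],
                "C": self.arrow_positions[:, 1],
                "uR": self.arrow_directions[:, 0],
                "uC": self.arrow_directions[:, 1],
                "magnitude": self.arrow_magnitudes,
            }
        ).to_csv(os.path.join(directory, "vector_field.csv"), index=False)
        for K, poly in self.attractors.items():
            pd.DataFrame({"R": poly[:, 0], "C": poly[:, 1]}).to_csv(
                os.path.join(directory, f"attractor_K_{K:.6g}.csv"), index=False
            )
        if self.overlay is not None:
            pd.DataFrame({"R": self.overlay[:, 0], "C": self.overlay[:, 1]}).to_csv(
                os.path.join(directory, "forced_trajectory.csv"), index=False
            )


def _attractor_polyline(m: ModelParams, K: float) -> np.ndarray:
    """Deterministic attractor at K: a point, or one limit-cycle period."""
    from .experiments import limit_cycle_period  # local import avoids a cycle
    from .simulate import SimProtocol, default_initial_conditions, integrate

    eq = interior_equilibrium(m, K)
    if K <= k_hopf(m):
        return np.array([[eq.R_star, eq.C_star]])
    mk = m.with_K(K)
    cyc = limit_cycle_period(m, K)
    t_transient = 3000.0
    proto = SimProtocol(
        t_total=t_transient + 2.0 * cyc.period,
        t_transient=t_transient,
        sample_dt=cyc.period / 1000.0,
    )
    traj = integrate(mk, ForcingSpec.unforced(), default_initial_conditions(mk), proto)
    tail = traj.slice(traj.times[-1] - cyc.period, traj.times[-1])
    ts = np.linspace(tail.times[0], tail.times[-1], ATTRACTOR_POINTS)
    return np.column_stack(
        [np.interp(ts, tail.times, tail.R), np.interp(ts, tail.times, tail.C)]
    )


def vector_field_grid(
    m: ModelParams,
    K: float,
    bounds: tuple[tuple[float, float], tuple[float, float]],
    n: int = 15,
):
    """Normalized arrow grid of the unforced vector field at static ``K``.

    Returns (positions, unit directions, magnitudes); zero-magnitude points
    (equilibria) get zero direction vectors.
    """
    (R_lo, R_hi), (C_lo, C_hi) = bounds
    if R_lo < 0 or C_lo < 0 or R_hi <= R_lo or C_hi <= C_lo:
        raise ValueError(f"invalid phaseplane bounds {bounds!r}")
    if n < 2:
        raise ValueError("need at least a 2x2 arrow grid")
    Rs = np.linspace(R_lo, R_hi, n)
    Cs = np.linspace(C_lo, C_hi, n)
    f0 = ForcingSpec.unforced()
    mk = m.with_K(K)
    pos, vec = [], []
    for R in Rs:
        for C in Cs:
            dR, dC = vector_field(mk, f0, State(R=float(R), C=float(C)), 0.0)
            pos.append((R, C))
            vec.append((dR, dC))
    pos = np.array(pos)
    vec = np.array(vec)
    mag = np.hypot(vec[:, 0], vec[:, 1])
    unit = np.zeros_like(vec)
    nz = mag > 0
    unit[nz] = vec[nz] / mag[nz, None]
    return pos, unit, mag


def build_portrait(
    m: ModelParams,
    f: ForcingSpec,
    traj: Trajectory | None = None,
    K_refs=None,
    bounds=None,
    n_arrows: int = 15,
    n_isocline: int = 400,
) -> PhasePortrait:
    """Full phase portrait: isoclines, arrows, reference attractors, overlay.

    Default reference capacities are the trough, mean and crest of the
    forcing cycle, ``(K_mean - A, K_mean, K_mean + A)``; each must exceed R*
    for its attractor to exist.  The arrow grid and resource isocline are
    drawn at K_mean.
    """
    R_star = consumer_isocline_R(m)
    if K_refs is None:
        K_refs = (m.K_mean - f.A, m.K_mean, m.K_mean + f.A)
    for K in K_refs:
        if not R_star < K <= m.K_mean + f.A:
            raise NoCoexistenceError(
                f"reference capacity K={K:.6g} outside (R*={R_star:.6g}, "
                f"K_mean+A={m.K_mean + f.A:.6g}]"
            )

    overlay = None
    if traj is not None:
        win = asymptotic_window(traj)
        overlay = np.column_stack([win.R, win.C])

    attractors = {float(K): _attractor_polyline(m, float(K)) for K in dict.fromkeys(K_refs)}

    if bounds is None:
        C_tops = [poly[:, 1].max() for poly in attractors.values()]
        if overlay is not None:
            C_tops.append(float(overlay[:, 1].max()))
        bounds = (
            (0.0, 1.1 * (m.K_mean + f.A)),
            (0.0, 1.5 * max(C_tops)),
        )

    R_grid = np.linspace(1e-9, bounds[0][1], n_isocline)
    iso_C = resource_isocline(m, m.K_mean, R_grid)
    pos, unit, mag = vector_field_grid(m, m.K_mean, bounds, n_arrows)
    return PhasePortrait(
        R_grid=R_grid,
        resource_isocline_C=np.asarray(iso_C),
        consumer_isocline_R=R_star,
        arrow_positions=pos,
        arrow_directions=unit,
        arrow_magnitudes=mag,
        attractors=attractors,
        overlay=overlay,
        bounds=bounds,
    )


def render_portrait(portrait: PhasePortrait, path=None, title: str | None = None):
    """Optional matplotlib rendering of a portrait (returns the figure).

    Reference attractors follow the trough/mean/crest colour convention
    (green, orange, purple) in ascending K order.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.plot(
        portrait.R_grid,
        portrait.resource_isocline_C,
        color="0.4",
        lw=1.2,
        label="resource isocline",
    )
    ax.axvline(portrait.consumer_isocline_R, color="0.4", ls="--", lw=1.2,
               label="consumer isocline")
    ax.quiver(
        portrait.arrow_positions[:, 0],
        portrait.arrow_positions[:, 1],
        portrait.arrow_directions[:, 0],
        portrait.arrow_directions[:, 1],
        portrait.arrow_magnitudes,
        cmap="Greys",
        alpha=0.5,
        width=0.003,
    )
    colors = ["tab:green", "tab:orange", "tab:purple"]
    for color, (K, poly) in zip(colors, sorted(portrait.attractors.items())):
        if len(poly) == 1:
            ax.plot(*poly[0], "o", color=color, ms=6, label=f"attractor K={K:.3g}")
        else:
            ax.plot(poly[:, 0], poly[:, 1], color=color, lw=1.5,
                    label=f"attractor K={K:.3g}")
    if portrait.overlay is not None:
        ax.plot(portrait.overlay[:, 0], portrait.overlay[:, 1], color="k", lw=0.5,
                alpha=0.7, label="forced trajectory")
    ax.set_xlim(*portrait.bounds[0])
    ax.set_ylim(*portrait.bounds[1])
    ax.set_xlabel("resource density R")
    ax.set_ylabel("consumer density C")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7, loc="upper right")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
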
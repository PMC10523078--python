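"""Numerical experiments: period sweeps, cycle periods, bifurcation scans, zones.

These drive the simulation and metric machinery across grids of forcing
speeds to reproduce the qualitative anatomy of the forced system:

* a *stabilizing phase* at fast forcing (ΔCV < 0),
* a *tongue of destabilization* and complex coupled-oscillator dynamics at
  moderate-to-slow forcing,
* and, at the slowest speeds, relaxation-like cycles that track the moving
  attractor.

The zone classifier (labels 1–5: stabilized, R-cycles, C–R cycles, C-cycles,
max/boundary cycles) is an explicitly heuristic, threshold-based summary of
amplitude and equilibrium-tracking diagnostics; the thresholds are exposed in
:class:`ZoneThresholds`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .exceptions import CRForceError, NoCycleError
from .model import (
    ForcingSpec,
    ModelParams,
    carrying_capacity,
    interior_equilibrium,
    k_hopf,
)
from .simulate import (
    SimProtocol,
    Trajectory,
    asymptotic_window,
    default_initial_conditions,
    default_protocol,
    integrate,
    sampling_window_length,
)

__all__ = [
    "SweepTable",
    "CyclePeriod",
    "ZoneMetrics",
    "ZoneThresholds",
    "period_sweep",
    "limit_cycle_period",
    "bifurcation_scan",
    "cluster_maxima",
    "zone_metrics",
    "classify_zone",
    "intrinsic_period",
]

logger = logging.getLogger(__name__)

#: prominence floor for peak detection, as a fraction of the series range;
#: rejects solver ripple without suppressing genuine period-doubled peaks.
PEAK_PROMINENCE_FRAC = 0.01


# ---------------------------------------------------------------------------
# deterministic limit-cycle period
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CyclePeriod:
    """Mean peak-to-peak period of a deterministic limit cycle."""

    period: float
    sd: float
    n_intervals: int

    @property
    def converged(self) -> bool:
        """Relative spread of the intervals below 1% certifies convergence."""
        return self.sd / self.period < 0.01

    def __float__(self) -> float:
        return self.period


def _refined_peak_times(t: np.ndarray, x: np.ndarray, prominence: float) -> np.ndarray:
    """Peak times with sub-sample parabolic refinement."""
    idx, _ = find_peaks(x, prominence=prominence)
    idx = idx[(idx > 0) & (idx < len(x) - 1)]
    if idx.size == 0:
        return np.empty(0)
    dt = t[1] - t[0]
    y0, y1, y2 = x[idx - 1], x[idx], x[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    shift = np.where(denom != 0.0, 0.5 * (y0 - y2) / denom, 0.0)
    return t[idx] + np.clip(shift, -1.0, 1.0) * dt


def limit_cycle_period(
    m: ModelParams,
    K: float | None = None,
    *,
    t_transient: float = 3000.0,
    min_intervals: int = 20,
    perturbation: float = 0.01,
) -> CyclePeriod:
    """Intrinsic period of the unforced limit cycle at carrying capacity ``K``.

    Integrates the autonomous system from a small perturbation of the
    equilibrium, discards the transient, and averages at least
    ``min_intervals`` consecutive peak-to-peak intervals of the resource
    series (peaks refined by parabolic interpolation).

    Raises
    ------
    NoCycleError
        If ``K <= K_Hopf`` (the equilibrium is stable: no cycle), or if the
        post-transient oscillation amplitude is below tolerance.
    """
    if K is None:
        K = m.K_mean
    mk = m.with_K(K)
    kh = k_hopf(m)
    if K <= kh:
        raise NoCycleError(f"K={K:.6g} <= K_Hopf={kh:.6g}: no limit cycle")

    # linearization period sets the scale for run length and sampling
    eq = interior_equilibrium(mk, K)
    guess = 2.0 * math.pi / abs(eq.lambda_im) if eq.lambda_im else 10.0
    window = max((min_intervals + 10) * guess, 200.0)
    proto = SimProtocol(
        t_total=t_transient + window,
        t_transient=t_transient,
        sample_dt=min(guess / 200.0, 0.05),
    )
    s0 = default_initial_conditions(mk, perturbation)
    traj = integrate(mk, ForcingSpec.unforced(), s0, proto)
    tail = traj.slice(t_transient, traj.times[-1])

    amp = float(tail.R.max() - tail.R.min())
    if amp < 1e-6:
        raise NoCycleError(
            f"post-transient resource amplitude {amp:.3g} below tolerance; "
            "no sustained cycle detected"
        )
    peaks = _refined_peak_times(tail.times, tail.R, PEAK_PROMINENCE_FRAC * amp)
    if peaks.size < min_intervals + 1:
        raise NoCycleError(
            f"only {peaks.size} peaks detected; need {min_intervals + 1}"
        )
    intervals = np.diff(peaks)[-min_intervals:]
    return CyclePeriod(
        period=float(intervals.mean()),
        sd=float(intervals.std(ddof=0)),
        n_intervals=int(intervals.size),
    )


def intrinsic_period(m: ModelParams, K: float | None = None) -> float:
    """Characteristic period of the unforced dynamics at ``K``.

    The limit-cycle period above the Hopf point; below it, the damped
    oscillation period ``2π/|Im λ|`` (infinite — returned as inf — if the
    equilibrium is non-excitable).
    """
    if K is None:
        K = m.K_mean
    if K > k_hopf(m):
        return limit_cycle_period(m, K).period
    eq = interior_equilibrium(m, K)
    return 2.0 * math.pi / abs(eq.lambda_im) if eq.excitable else math.inf


# ---------------------------------------------------------------------------
# forcing-period sweep
# ---------------------------------------------------------------------------


@dataclass
class SweepTable:
    """Long-format stability records across a grid of forcing speeds."""

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.12g")


def period_sweep(
    m: ModelParams,
    A: float,
    p_grid,
    proto_factory=default_protocol,
    classify: bool = False,
) -> SweepTable:
    """ΔCV and λ_total across forcing speeds, ordered by forcing period 1/p.

    ``proto_factory(f)`` supplies the protocol per grid point (the
    study-fidelity :func:`default_protocol` unless a scaled-down factory is
    given).  Failures at individual grid points are logged and recorded as
    NaN rows rather than aborting the sweep.
    """
    from .stability import asymptotic_cv, lambda_total

    p_grid = np.sort(np.asarray(p_grid, dtype=float))[::-1]  # slow last
    # The unforced reference is autonomous, so its CV depends only on the
    # protocol and the window length; cache it across grid points.
    unforced_cache: dict[tuple, tuple[float, float]] = {}

    def unforced_cv(f: ForcingSpec, proto: SimProtocol) -> tuple[float, float]:
        key = (proto, sampling_window_length(f))
        if key not in unforced_cache:
            unforced_cache[key] = asymptotic_cv(m, ForcingSpec(A=0.0, p=f.p), proto)
        return unforced_cache[key]

    records = []
    for p in p_grid:
        f = ForcingSpec(A=A, p=float(p))
        rec = {"p": float(p), "forcing_period": 1.0 / p}
        try:
            proto = proto_factory(f)
            cv_C_f, cv_R_f = asymptotic_cv(m, f, proto)
            cv_C_u, cv_R_u = unforced_cv(f, proto)
            try:
                lam_tot = lambda_total(m, f)
            except CRForceError:
                lam_tot = math.nan
            rec.update(
                delta_cv_C=cv_C_f - cv_C_u,
                delta_cv_R=cv_R_f - cv_R_u,
                cv_C_forced=cv_C_f,
                cv_R_forced=cv_R_f,
                lambda_total=lam_tot,
            )
            if classify:
                zm = zone_metrics(m, f, proto_factory(f))
                rec["zone"] = classify_zone(
                    zm, 1.0 / p, intrinsic_period(m, m.K_mean)
                )
        except CRForceError as err:
            logger.warning("sweep point p=%g failed: %s", p, err)
            rec.update(
                delta_cv_C=math.nan,
                delta_cv_R=math.nan,
                cv_C_forced=math.nan,
                cv_R_forced=math.nan,
                lambda_total=math.nan,
                error=str(err),
            )
        records.append(rec)
    frame = pd.DataFrame.from_records(records).sort_values("forcing_period")
    meta = {
        "A": A,
        "params": m,
        "p_grid": [float(p) for p in p_grid],
    }
    return SweepTable(frame=frame.reset_index(drop=True), metadata=meta)


# ---------------------------------------------------------------------------
# bifurcation scan over forcing speed
# ---------------------------------------------------------------------------


def cluster_maxima(values, resolution: float = 1e-4) -> np.ndarray:
    """Cluster means of sorted local-maxima values, merging gaps < resolution."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        return v
    splits = np.where(np.diff(v) > resolution)[0] + 1
    return np.array([c.mean() for c in np.split(v, splits)])


def bifurcation_scan(
    m: ModelParams,
    A: float,
    p_grid,
    proto_factory=default_protocol,
    resolution: float = 1e-4,
    stroboscopic: bool = False,
) -> pd.DataFrame:
    """Attractor complexity versus forcing speed.

    For each p, collect the local maxima of the consumer series over the
    asymptotic window and deduplicate them at ``resolution``: one cluster
    marks a period-1 entrained orbit, 2ⁿ clusters a period-doubled cascade,
    and many clusters the complex/chaotic regimes.  With
    ``stroboscopic=True`` the consumer density is instead sampled once per
    forcing period (classic stroboscopic section).

    Returns a long-format frame with one row per (p, maximum-cluster).
    """
    rows = []
    for p in np.sort(np.asarray(p_grid, dtype=float))[::-1]:
        f = ForcingSpec(A=A, p=float(p))
        try:
            traj = integrate(m, f, proto=proto_factory(f))
            win = asymptotic_window(traj, f)
            if stroboscopic:
                t0 = win.times[0]
                phases = np.arange(t0, win.times[-1], 1.0 / p)
                vals = np.interp(phases, win.times, win.C)
            else:
                amp = float(win.C.max() - win.C.min())
                idx, _ = find_peaks(win.C, prominence=PEAK_PROMINENCE_FRAC * max(amp, 1e-12))
                vals = win.C[idx]
                if vals.size == 0:  # flat (entrained to equilibrium-like orbit)
                    vals = np.array([float(win.C.max())])
            for c in cluster_maxima(vals, resolution):
                rows.append({"p": float(p), "forcing_period": 1.0 / p, "C_max": float(c)})
        except CRForceError as err:
            logger.warning("bifurcation point p=%g failed: %s", p, err)
            rows.append({"p": float(p), "forcing_period": 1.0 / p, "C_max": math.nan})
    return pd.DataFrame(rows).sort_values(["forcing_period", "C_max"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# zone metrics and heuristic classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ZoneMetrics:
    """Amplitude and tracking diagnostics of one forced asymptotic orbit.

    ``amp_*`` are peak-to-trough amplitudes over the asymptotic window;
    ``amp_*_ref`` those of the deterministic attractor at K_mean, and
    ``max_*_hi`` the maxima of the deterministic attractor at the top of the
    forcing cycle (K_mean + A).  ``tracking_error`` is the mean Euclidean
    distance of the trajectory from the instantaneous moving equilibrium,
    normalized by the norm of the K_mean equilibrium.
    """

    amp_R: float
    amp_C: float
    amp_R_ref: float
    amp_C_ref: float
    tracking_error: float
    max_R: float
    max_C: float
    max_R_hi: float
    max_C_hi: float
    forcing_amplitude: float


@dataclass(frozen=True)
class ZoneThresholds:
    """Config-exposed thresholds of the heuristic zone classifier."""

    quiet: float = 0.10  # both amplitudes below this fraction of reference -> zone 1
    active: float = 0.25  # an axis counts as responding above this fraction
    c_dominant: float = 0.50  # consumer amplitude fraction for zone 4
    track_low: float = 0.25  # normalized tracking error regarded as "locked on"
    boundary_match: float = 0.10  # rel. mismatch of extrema vs K_max attractor, zone 5


def _attractor_extrema(m: ModelParams, K: float) -> tuple[float, float, float, float]:
    """(amp_R, amp_C, max_R, max_C) of the deterministic attractor at K."""
    if K <= k_hopf(m):
        eq = interior_equilibrium(m, K)
        return 0.0, 0.0, eq.R_star, eq.C_star
    mk = m.with_K(K)
    guess = intrinsic_period(m, K)
    proto = SimProtocol(
        t_total=3000.0 + 30.0 * guess,
        t_transient=3000.0,
        sample_dt=min(guess / 200.0, 0.05),
    )
    traj = integrate(mk, ForcingSpec.unforced(), default_initial_conditions(mk), proto)
    tail = traj.slice(3000.0, traj.times[-1])
    return (
        float(tail.R.max() - tail.R.min()),
        float(tail.C.max() - tail.C.min()),
        float(tail.R.max()),
        float(tail.C.max()),
    )


def zone_metrics(
    m: ModelParams, f: ForcingSpec, proto: SimProtocol | None = None
) -> ZoneMetrics:
    """Amplitude/tracking diagnostics of the forced orbit for classification."""
    if proto is None:
        proto = default_protocol(f)
    traj = integrate(m, f, proto=proto)
    win = asymptotic_window(traj, f)

    amp_R = float(win.R.max() - win.R.min())
    amp_C = float(win.C.max() - win.C.min())
    amp_R_ref, amp_C_ref, _, _ = _attractor_extrema(m, m.K_mean)
    _, _, max_R_hi, max_C_hi = _attractor_extrema(m, m.K_mean + f.A)

    eq0 = interior_equilibrium(m, m.K_mean)
    scale = math.hypot(eq0.R_star, eq0.C_star)
    Ks = np.array([carrying_capacity(m, f, t) for t in win.times])
    R_star = eq0.R_star  # K-invariant
    valid = Ks > R_star
    C_star = np.full_like(Ks, math.nan)
    C_star[valid] = (
        -m.r * (m.b + R_star) * (R_star - Ks[valid]) / (m.a * Ks[valid])
    )
    dist = np.hypot(win.R[valid] - R_star, win.C[valid] - C_star[valid])
    tracking = float(dist.mean()) / scale if dist.size else math.nan

    return ZoneMetrics(
        amp_R=amp_R,
        amp_C=amp_C,
        amp_R_ref=amp_R_ref,
        amp_C_ref=amp_C_ref,
        tracking_error=tracking,
        max_R=float(win.R.max()),
        max_C=float(win.C.max()),
        max_R_hi=max_R_hi,
        max_C_hi=max_C_hi,
        forcing_amplitude=f.A,
    )


def classify_zone(
    zm: ZoneMetrics,
    forcing_period: float,
    intrinsic_period: float,
    thresholds: ZoneThresholds = ZoneThresholds(),
) -> int | str:
    """Heuristic dynamical-zone label (1–5) for a forced orbit.

    Rule cascade (first match wins); zones are defined only under forcing,
    so A = 0 is explicitly ``"unclassifiable"``:

    1. both amplitudes quiet relative to the K_mean attractor (stabilized),
    2. resource responding while the consumer stays quiet (R-cycles),
    4. consumer-dominated response with low tracking error (C-cycles),
    5. trajectory extrema matching the attractor at the top of the K cycle
       (max/boundary relaxation-like cycles),
    3. both axes responding with poor equilibrium tracking (coupled C–R
       cycles, the destabilized tongue).
    """
    th = thresholds
    if zm.forcing_amplitude == 0.0:
        return "unclassifiable"
    vals = [zm.amp_R, zm.amp_C, zm.tracking_error, zm.amp_R_ref, zm.amp_C_ref]
    if not all(math.isfinite(v) for v in vals):
        return "unclassifiable"

    # amplitude fractions relative to the K_mean attractor; below the Hopf
    # point the reference attractor is a point, so use the K_max attractor
    # maxima as scale instead of dividing by zero.
    ref_R = zm.amp_R_ref if zm.amp_R_ref > 0 else zm.max_R_hi
    ref_C = zm.amp_C_ref if zm.amp_C_ref > 0 else zm.max_C_hi
    frac_R = zm.amp_R / ref_R if ref_R > 0 else math.inf
    frac_C = zm.amp_C / ref_C if ref_C > 0 else math.inf

    if frac_R < th.quiet and frac_C < th.quiet:
        return 1
    if frac_R > th.active and frac_C < th.active:
        return 2
    if (
        frac_R < th.active
        and frac_C > th.c_dominant
        and zm.tracking_error < th.track_low
    ):
        return 4
    if (
        abs(zm.max_R - zm.max_R_hi) <= th.boundary_match * zm.max_R_hi
        and abs(zm.max_C - zm.max_C_hi) <= th.boundary_match * zm.max_C_hi
        and forcing_period > intrinsic_period
    ):
        return 5
    if frac_R > th.active and frac_C > th.active:
        return 3
    return "unclassifiable"
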
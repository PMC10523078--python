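# Methods

## Model and assumptions

The deterministic skeleton is the Rosenzweig–MacArthur consumer–resource
model: logistic resource growth, Holling type II consumption, linear
consumer mortality. Environmental periodicity enters only through the
carrying capacity, `K(t) = K_mean + A sin(2π p t)` — the simplest
continuously differentiable stand-in for highly autocorrelated environmental
variation. Forcing any other rate (attack rate, mortality, efficiency) is
out of scope here, though the phaseplane machinery would carry over to any
parameter with a qualitatively similar effect on the equilibrium.

Key structural facts the code exploits:

* The consumer nullcline is vertical at `R* = db/(ae − d)`; it does not move
  with K. A valid parameter set therefore requires `ae > d`, and coexistence
  requires `K > R*`; both are enforced at construction/call time.
* The resource nullcline is a hump with its `C = 0` intercept exactly at
  `R = K`; raising K stretches it, moving the interior equilibrium **only in
  the consumer direction**.
* The Jacobian at the interior equilibrium has a structurally zero
  lower-right entry, its trace gives the closed-form dominant-eigenvalue
  real part on the excitable (complex) branch, and setting that to zero
  yields `K_Hopf = b(d + ae)/(ae − d)` — independent of r, linear in b.
* On the excitable branch `λ_max(K) = α − β/K` with
  `β = rbd(ae + d)/(2ae(ae − d)) > 0`: increasing, concave, the "checkmark"
  right arm. Below the branch point (found by bisection on the discriminant)
  the eigenvalues are real and the larger root is used; the two branches
  join continuously (with square-root slope).

## Stability metrics

**λ_total** integrates `λ_max(K(t)) − λ_max(K_mean)` over one forcing cycle
by adaptive quadrature (`scipy.integrate.quad`, quarter-period breakpoints,
absolute error required below 1e-10; the integrand is analytic in t except
at isolated branch-point crossings, which it passes continuously). The
concavity of `λ_max(K)` makes λ_total strictly negative whenever
`K_mean − A` stays above the checkmark bottom; on the purely excitable
branch it reduces to the closed form
`λ_total = (β/p)(1/K_mean − 1/sqrt(K_mean² − A²))`, which one test uses as
an independent oracle. The exact `1/p` scaling (change of variables
`u = pt`) is asserted to 1e-8 relative. If the forcing trough reaches `R*`
the interior equilibrium ceases to exist mid-cycle and the function raises
rather than extrapolate.

**CV metrics** use the population (divide-by-n) standard deviation over the
dense, evenly sampled terminal window; on thousands of samples of a periodic
orbit the n vs n−1 distinction is orders of magnitude below every tolerance
used, but the convention is fixed once here. CVs are computed on the
solver's dense output grid, never on its internal adaptive steps, so step
clustering near fast excursions cannot bias the statistics. ΔCV compares the
forced run against the unforced (`A = 0`) run under the *same* protocol and
window; at `A = 0` the two runs are identical and ΔCV is exactly zero — a
useful self-test of the bookkeeping.

## Simulation protocol

* Integrator: `scipy.integrate.solve_ivp` with LSODA — adaptive step-size
  control with automatic Adams/BDF switching, so slow-forcing regimes that
  become locally stiff (long relaxation excursions near the axes) are
  handled without user intervention. Any `solve_ivp` method name can be
  substituted via `SimProtocol.method`; CV results are insensitive to the
  choice at the default tolerances (asserted: halving tolerances moves the
  asymptotic CV by < 1e-4).
* Default tolerances `rel_tol = 1e-9`, `abs_tol = 1e-11`; when `A > 0` the
  step size is additionally capped at a quarter forcing period so the solver
  can never stride over an environmental oscillation.
* Sampling grid `sample_dt = min(0.01/p, 0.05)`: resolves both the intrinsic
  cycles (periods ≳ 4) and the forcing envelope at fast p.
* Transients: 5 000 time units for `p ≥ ~1`, growing like `9/p` and capped
  at 90 000 at the slow end of the studied range; total span at least
  50 000 time units and always transient + sampling window. The CV window is
  `max(4/p, 1000)` time units at the end of the run — four environmental
  cycles, or 1000 time units when forcing is fast.
* "Time steps" throughout mean model time units, not solver steps (the
  window formulas `4/p` and 1000 only make sense in time units).
* Initial conditions: the interior equilibrium at `K_mean` perturbed
  multiplicatively by +1% in both coordinates. The model itself never
  states initial conditions in a way that matters asymptotically (the
  attractors are global within the positive quadrant for the regimes
  studied); a deterministic perturbation avoids seeds entirely, and a test
  checks that 0.5% vs 2% perturbations change the measured limit-cycle
  period by < 0.1%.
* Negative densities within `10 × abs_tol` below zero are clipped to zero
  with a warning (solver ripple during deep troughs); anything lower is
  reported as an integration failure with the failure time.

## Experiments

**Limit-cycle period** (above `K_Hopf` only; below it the code raises
`NoCycleError`, or reports the damped-oscillation period `2π/|Im λ|` via
`intrinsic_period`): mean of ≥ 20 consecutive peak-to-peak intervals of R
after a 3 000-unit transient, peaks found with a prominence floor of 1% of
the series range and refined by parabolic interpolation; a relative interval
spread < 1% certifies convergence. At the standard rates and
`K = K_Hopf + 0.05` this yields 14.60, 8.01, 5.68 and 4.05 time units for
r = 1.5, 5, 10, 20 — close to the linearization periods `2π/|Im λ|` (14.30,
7.83, 5.54, 3.92), as expected just above a Hopf point.

**Period sweeps** evaluate ΔCV and λ_total on a grid of forcing speeds,
ordered by forcing period. The unforced reference run is cached per
(protocol, window length) since it is autonomous. Failures at individual
grid points (e.g. a window that does not fit a user-supplied protocol) are
recorded as NaN rows with the error message, never fatal.

**Bifurcation scans** collect local maxima of the consumer series over the
asymptotic window and merge them into clusters at an absolute resolution of
1e-4: one cluster = period-1 entrained orbit, 2ⁿ = period-doubled, many =
complex/chaotic regimes. Maxima (rather than stroboscopic sampling at the
forcing phase) are the default because they are robust to phase drift; a
stroboscopic mode is available behind a flag. No Lyapunov exponents are
computed — chaos is diagnosed only at this descriptive level.

**Zone classification** is an explicitly heuristic, threshold-based summary
(thresholds in `ZoneThresholds`, all config-exposed): zone 1 when both
amplitude ratios against the K_mean attractor are below 10%; zone 2 when the
resource responds (> 25%) but the consumer does not (< 25%); zone 4 when the
response is consumer-dominated (> 50%) with small resource amplitude and a
normalized equilibrium-tracking error below 0.25; zone 5 when the
trajectory's extrema match the deterministic attractor at the crest of the K
cycle within 10% (and forcing is slower than the intrinsic cycle); zone 3
when both axes respond and tracking is poor. Rules are evaluated in the
order 1, 2, 4, 5, 3 and return `"unclassifiable"` for `A = 0` (zones are
defined only under forcing) or on conflicts. The tracking error is the mean
Euclidean distance from the instantaneous moving equilibrium
`(R*, C*(K(t)))`, normalized by the norm of the K_mean equilibrium. With the
default thresholds the representative speeds p = 0.5, 0.125, 0.02, 0.002
(r = 10, A = 0.5) classify as zones 2–5, and fast forcing (p = 2) as zone 1.

**Phase portraits** bundle the isoclines at K_mean, a magnitude-normalized
vector-field arrow grid, the deterministic reference attractors at the
trough, mean and crest of the K cycle (a point below `K_Hopf`, otherwise one
post-transient cycle period resampled to 500 points), and the asymptotic
window of a forced trajectory. Default bounds are
`[0, 1.1(K_mean + A)] × [0, 1.5 × max C]`, overridable.

## Problem sizes used in the shipped tests and acceptance script

The protocol defaults above are study-fidelity; the shipped test suite and
acceptance script run the same machinery at reduced spans chosen so every
qualitative result is already asymptotic: 6 000-unit runs with 5 000-unit
transients and `rel_tol = 1e-6` for forced-CV work (the CV is
tolerance-converged to < 1e-4 at that setting, which a test asserts), a
10-point forcing-period grid for the two-phase sweep, and 20 peak intervals
for period estimation. The acceptance script's four runs complete in
seconds.

## What the tests do and do not show

All quantitative checks concern this one deterministic model under pure
sinusoidal forcing. They say nothing about noisy or multi-frequency
environments, about forcing of rates other than productivity, about other
functional responses, or about extinction (densities are continuous and the
model has no demographic stochasticity). The zone labels are descriptive
conveniences for navigating parameter space, not dynamical invariants; their
boundaries move with the thresholds and with r.

## Known limitations

* Near-degenerate regimes (K within ~1e-3 of `K_Hopf`, or forcing troughs
  grazing the checkmark bottom) converge slowly; the default `K_Hopf + 0.05`
  offset used by the presets avoids the degeneracy at the bifurcation
  itself.
* The bifurcation cluster count at resolution 1e-4 can over-count for
  orbits with very slowly drifting maxima (quasiperiodic entrainment); treat
  counts > 2 as "complex", not as exact periodicities.
* `limit_cycle_period` assumes the cycle is reached from the default 1%
  perturbation within the transient; extremely slow growth rates (r ≪ 1)
  may need a longer `t_transient`.
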
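"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`CRForceError`, so callers (and the CLI) can distinguish model-domain
failures from programming errors.
"""


class CRForceError(Exception):
    """Base class for all crforce errors."""


class ParameterError(CRForceError, ValueError):
    """Invalid or degenerate model parameters (e.g. a*e <= d, negative rates)."""


class AmplitudeError(ParameterError):
    """Forcing amplitude at least as large as the mean carrying capacity.

    K(t) = K_mean + A*sin(2*pi*p*t) would touch or cross zero, i.e. the
    environment would have non-positive productivity for part of the cycle.
    """


class NoCoexistenceError(CRForceError, ValueError):
    """No positive interior equilibrium at the requested carrying capacity."""


class EquilibriumLossError(CRForceError, ValueError):
    """The forcing cycle drives K below the coexistence threshold R*."""


class NoCycleError(CRForceError, RuntimeError):
    """A limit cycle was requested below the Hopf point (or none was detected)."""


class SolverError(CRForceError, RuntimeError):
    """The ODE integrator failed (step-size collapse or runaway negativity)."""

    def __init__(self, message: str, t_failure: float | None = None):
        super().__init__(message)
        self.t_failure = t_failure


class WindowError(CRForceError, ValueError):
    """The requested sampling window does not fit inside the simulated span."""


class ZeroMeanError(CRForceError, ValueError):
    """Coefficient of variation requested for a series with non-positive mean."""


class ConfigError(CRForceError, ValueError):
    """Malformed or inconsistent run configuration."""
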
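"""Exception hierarchy for coroflow.

Every error raised by the library derives from :class:`CoroflowError`, so
callers embedding the solver (e.g. the UQ pipeline, which must log and skip
individual failed simulations) can catch one base class.
"""


class CoroflowError(Exception):
    """Base class for all coroflow errors."""


class ParseError(CoroflowError):
    """A geometry / patient / waveform file could not be parsed."""


class TopologyError(CoroflowError):
    """Segment connectivity does not form a rooted bifurcating tree."""


class DiscretizationError(CoroflowError):
    """A segment cannot be gridded at the requested spacing."""


class ConsistencyError(CoroflowError):
    """Mutually inconsistent stenosis geometry (degree, rs, ru)."""


class DomainError(CoroflowError):
    """A physical quantity is outside its admissible domain."""


class ConfigError(CoroflowError):
    """Invalid configuration value (unknown dominance, variant, ...)."""


class InstabilityError(CoroflowError):
    """The time-marching scheme produced NaN / negative area, or the
    configured time step violates the CFL condition."""


class SolveError(CoroflowError):
    """A Newton solve at a junction / stenosis / boundary failed."""


class ConvergenceError(CoroflowError):
    """Periodic convergence was not reached, or a result that requires a
    converged simulation was requested from a non-converged one."""


class PlacementError(CoroflowError):
    """The distal pressure probe cannot be placed (downstream tree too
    short)."""


class DesignError(CoroflowError):
    """Invalid sampling-design request (k < 2, m < 2, ...)."""


class DegenerateError(CoroflowError):
    """Zero output variance: Sobol indices are undefined."""


class PipelineError(CoroflowError):
    """Too many individual simulation failures inside a UQ campaign."""
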
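"""Exception hierarchy.

All package errors derive from :class:`GWTauError` so callers can catch one
type. Input/parameter problems additionally derive from ``ValueError`` and
computational failures from ``RuntimeError``, matching common numpy/scipy
practice.
"""


class GWTauError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(GWTauError, ValueError):
    """Malformed data: non-finite coordinates, mismatched shapes, bad files."""


class InvalidParameterError(GWTauError, ValueError):
    """Out-of-range tuning parameter (e.g. Wasserstein exponent p < 1)."""


class InternalInvariantError(GWTauError, RuntimeError):
    """A structural invariant that must hold by construction was violated."""


class ComputationError(GWTauError, RuntimeError):
    """A numerical routine (LP solver, ODE integrator) failed."""
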
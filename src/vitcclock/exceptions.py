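"""Exception hierarchy.

Two branches matter for callers (and for the CLI's exit codes): problems
with the *inputs* (:class:`ClockValidationError`, exit status 2) and
problems arising during *numerics* (:class:`ClockNumericalError`, exit
status 3).
"""


class ClockError(Exception):
    """Base class for all package errors."""


class ClockValidationError(ClockError, ValueError):
    """Invalid parameters, states or datasets."""


class ClockNumericalError(ClockError, RuntimeError):
    """Failures of the numerical machinery (solver, event location)."""


class InvalidStateError(ClockValidationError):
    """A concentration state is negative beyond tolerance."""


class DegenerateParameterError(ClockValidationError):
    """Parameter combination at which a closed form breaks down (rho*phi = 1)."""


class OutOfValidityError(ClockValidationError):
    """An asymptotic solution was evaluated outside its validity interval."""


class NoSwitchoverError(ClockValidationError):
    """rho*phi >= 1: the inhibitor never runs out, no induction period exists."""


class NoInductionError(ClockValidationError):
    """c0 <= phi*m0: no induction period for this recipe/condition."""


class IdentifiabilityError(ClockValidationError):
    """Dataset lacks the distinct conditions needed to fit (k0, phi)."""


class FixtureIntegrityError(ClockValidationError):
    """Packaged data file does not match its recorded checksum."""


class SolverError(ClockNumericalError):
    """The ODE solver reported failure; carries its diagnostic message."""


class SwitchoverNotReachedError(ClockNumericalError):
    """No threshold crossing inside the simulated window (window too short)."""
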
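"""Exception hierarchy for icpsde.

All library errors derive from :class:`IcpsdeError` so callers (and the
CLI) can catch everything the package signals with one clause.
"""

from __future__ import annotations


class IcpsdeError(Exception):
    """Base class for all errors signalled by icpsde."""


class ParameterError(IcpsdeError, ValueError):
    """A physiological parameter violates its invariant.

    The message names the offending field.
    """


class DomainError(IcpsdeError, ValueError):
    """An operation was evaluated outside its mathematical domain."""


class NoStationaryDistribution(IcpsdeError, ValueError):
    """The noise intensity is too large (or zero) for a stationary law."""


class PositivityBreachError(IcpsdeError, RuntimeError):
    """An Euler–Maruyama path crossed zero.

    Attributes
    ----------
    step_index : int
        Index of the first time step at which the pressure became
        non-positive.
    """

    def __init__(self, step_index: int, message: str | None = None):
        self.step_index = int(step_index)
        super().__init__(
            message
            or f"Euler-Maruyama path became non-positive at step {step_index}; "
            "use the 'log-euler' scheme or a smaller time step"
        )


class GridMismatchError(IcpsdeError, ValueError):
    """Time grids of two objects that must share a grid differ."""


class TrajectoryFormatError(IcpsdeError, ValueError):
    """A trajectory CSV file does not follow the declared dialect."""


class HorizonError(IcpsdeError, RuntimeError):
    """Too many Monte-Carlo paths were censored by the time horizon."""
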
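"""Exception hierarchy for the package."""

from __future__ import annotations

__all__ = [
    "IonstepError",
    "InvalidArgumentError",
    "UnsupportedModelError",
    "NumericalFailure",
    "ConstructionFailure",
    "RangeError",
    "StaleTableError",
]


class IonstepError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(IonstepError, ValueError):
    """An argument violates a documented precondition."""


class UnsupportedModelError(IonstepError):
    """A requested cell model is not available in this build."""


class NumericalFailure(IonstepError, ArithmeticError):
    """A non-finite value appeared during stepping.

    Attributes identify the offending location so long runs can be triaged.
    """

    def __init__(self, message: str, *, step: int | None = None,
                 cell: int | None = None, state: str | None = None):
        super().__init__(message)
        self.step = step
        self.cell = cell
        self.state = state


class ConstructionFailure(IonstepError):
    """A lookup table could not be built (non-finite entry, bad coefficient)."""

    def __init__(self, message: str, *, expression: str | None = None,
                 node: float | None = None):
        super().__init__(message)
        self.expression = expression
        self.node = node


class RangeError(IonstepError, ValueError):
    """A strict-policy table query fell outside the tabulated range."""

    def __init__(self, message: str, *, value: float | None = None,
                 bounds: tuple[float, float] | None = None):
        super().__init__(message)
        self.value = value
        self.bounds = bounds


class StaleTableError(IonstepError):
    """A lookup table built for one time step was used with another."""
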
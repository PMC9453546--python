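"""Exception hierarchy and logging setup shared across the package.

Exit-code mapping used by the CLI: schema/input problems -> 2,
fit/convergence problems -> 3.
"""

from __future__ import annotations

import logging

logger = logging.getLogger("hydrotraits")


class HydrotraitsError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class SchemaError(HydrotraitsError):
    """Malformed input table: unknown columns, bad signs, non-numeric cells."""

    exit_code = 2


class InvalidRecordError(HydrotraitsError):
    """A single record violates a physical precondition (e.g. zero denominator)."""

    exit_code = 2


class FitError(HydrotraitsError):
    """A model fit failed to converge or is unidentifiable."""

    exit_code = 3


class UnidentifiableBreakpointError(FitError):
    """Piecewise breakpoints collapsed onto each other or the data range edge."""

    def __init__(self, message: str, boundary: str | None = None):
        super().__init__(message)
        self.boundary = boundary


class NoIntersectionError(FitError):
    """Fitted line never meets the 1:1 line (infinite hydroscape or parallel phase)."""


class NoTurgorLossError(FitError):
    """No linear post-turgor-loss tail detectable in a pressure-volume series."""


class InsufficientDataError(HydrotraitsError):
    """Too few records for the requested operation."""

    exit_code = 2
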
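"""Exception hierarchy.

All package-specific failures derive from :class:`TMBGridError` so callers can
catch one base class; each also derives from the closest builtin so that code
written against generic ``ValueError``/``KeyError`` semantics keeps working.
"""


class TMBGridError(Exception):
    """Base class for all errors raised by tmbgrid."""


class InvalidArgumentError(TMBGridError, ValueError):
    """A scalar argument violates its precondition (negative TMB, zero panel, ...)."""


class OutOfGridError(TMBGridError, ValueError):
    """The observation implies a TMB beyond the grid's upper bound."""


class GridMismatchError(TMBGridError, ValueError):
    """Two distributions defined on different grids were combined."""


class DegeneratePosteriorError(TMBGridError, ValueError):
    """Prior and likelihood have disjoint support; the posterior is undefined."""


class CohortSchemaError(TMBGridError, ValueError):
    """A cohort file is missing a required column."""


class EmptyCohortError(TMBGridError, ValueError):
    """No valid rows remain after filtering a cohort file."""


class UnknownHistologyError(TMBGridError, KeyError):
    """The requested histology is absent from (or ambiguous in) the cohort."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0] if self.args else ""


class InsufficientDataError(TMBGridError, ValueError):
    """Too few cohort records for the requested statistic."""
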
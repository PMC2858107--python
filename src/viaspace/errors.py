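"""Exception hierarchy.

All package-specific failures derive from :class:`ViaspaceError` so callers
can distinguish domain errors from programming errors.
"""


class ViaspaceError(Exception):
    """Base class for all package errors."""


class UniverseFormatError(ViaspaceError):
    """A reaction table, environment or biomass file violates its format."""


class NonViableError(ViaspaceError):
    """An operation required a viable genotype and did not get one."""


class NoLegalSwapError(ViaspaceError):
    """A reaction swap was requested but no legal (out, in) pair exists."""


class SolverError(ViaspaceError):
    """The LP solver reported a numerical failure."""


class EnumerationBudgetError(ViaspaceError):
    """An exhaustive enumeration would exceed the combinatorial budget."""
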
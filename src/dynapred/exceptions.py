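"""Exception hierarchy.

All package errors derive from :class:`DynapredError` so callers can catch
one base class; the subclasses distinguish configuration mistakes, malformed
input files, empty inputs after filtering, numerical estimation failures and
out-of-domain arguments.
"""


class DynapredError(Exception):
    """Base class for all errors raised by dynapred."""


class ConfigurationError(DynapredError, ValueError):
    """A configuration object violates its invariants; names the field."""


class FormatError(DynapredError, ValueError):
    """An input file does not follow the expected tabular dialect."""


class EmptyInputError(DynapredError, ValueError):
    """An operation received (or produced) zero usable records."""


class EstimationError(DynapredError, RuntimeError):
    """A model fit failed: separation, non-convergence, collinearity."""


class DomainError(DynapredError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""
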
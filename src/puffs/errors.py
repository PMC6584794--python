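"""Exception hierarchy.

All data-level failures raised by this package derive from :class:`PuffsError`
so callers (and the CLI) can distinguish bad data (exit code 1) from bad usage
(exit code 2, handled by the argument parser).
"""


class PuffsError(Exception):
    """Base class for all data and domain errors raised by puffs."""


class ParseError(PuffsError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class StructuralError(PuffsError, ValueError):
    """Parsed data violates a structural invariant (e.g. non-monotone time)."""


class DomainError(PuffsError, ValueError):
    """A numeric input is outside the mathematical domain of an operation."""


class SingularDesignError(PuffsError, ValueError):
    """The regression design matrix is rank deficient; names the collinear columns."""
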
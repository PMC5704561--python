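"""Exception hierarchy.

All user-facing failures derive from :class:`PhyloscopeError` so the CLI can
map them to a user-error exit code; anything else is an internal error.
"""


class PhyloscopeError(Exception):
    """Base class for all phyloscope errors."""


class InvalidArgumentError(PhyloscopeError, ValueError):
    """A function was called with arguments violating its preconditions."""


class FormatError(PhyloscopeError, ValueError):
    """An input file is malformed."""


class EmptyProfileError(PhyloscopeError):
    """A profile was requested for an alignment with no usable columns."""


class EmptyFamilyError(PhyloscopeError):
    """Gene-family simulation lost every lineage."""


class UndefinedCorrelationError(PhyloscopeError):
    """Rank correlation undefined (zero variance on one side)."""
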
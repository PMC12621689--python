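"""Exception hierarchy.

All package errors derive from :class:`ConsensigError` so callers can catch
one base class; subclasses distinguish malformed files from contract
violations so the CLI can report them differently.
"""


class ConsensigError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ConsensigError):
    """A file does not conform to its declared on-disk format (GCT/GCTX)."""


class SchemaError(ConsensigError):
    """A table is missing required columns or has untypable fields."""


class ValidationError(ConsensigError):
    """Inputs violate a documented precondition or invariant."""


class EligibilityError(ValidationError):
    """A perturbagen does not meet the cell-line coverage requirement."""
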
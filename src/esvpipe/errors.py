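"""Exception hierarchy for esvpipe."""


class EsvPipeError(Exception):
    """Base class for all esvpipe errors."""


class InvalidGridError(EsvPipeError):
    """Grid specification violates its invariants (too small, bad cell size)."""


class AlignmentError(EsvPipeError):
    """Two rasters that must share a grid do not."""


class ConfigurationError(EsvPipeError):
    """A scenario / pipeline configuration is invalid."""


class DomainError(EsvPipeError):
    """An input value is outside the mathematically valid domain."""


class DegenerateInputError(EsvPipeError):
    """Input is too degenerate for the requested operation
    (e.g. fewer distinct values than classes, zero-variance target)."""


class SchemaError(EsvPipeError):
    """A table does not match the expected schema (labels, shape)."""
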
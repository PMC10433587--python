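"""Exception hierarchy shared across the pipeline stages."""


class MorindexError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(MorindexError, ValueError):
    """A parameter object (filter bank, pattern spec, ...) fails validation."""


class InvalidInputError(MorindexError, ValueError):
    """Input rasters/records are malformed or mutually inconsistent."""


class DegenerateClusteringError(MorindexError):
    """Fewer distinct feature vectors than requested clusters."""


class EmptyInputError(MorindexError):
    """An operation that needs at least one record received none."""


class InvalidStateError(MorindexError):
    """An object is used before a required stage (e.g. unclassified nuclei)."""
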
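"""Exception hierarchy shared across the package."""


class PvstratError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PvstratError):
    """An input file does not conform to the expected tabular layout."""


class ValidationError(PvstratError, ValueError):
    """Input data violates a documented invariant (bad count, bad id, ...)."""


class ConsistencyError(PvstratError):
    """Two inputs that must describe the same universe disagree."""


class GenerationError(PvstratError):
    """The synthetic-data generator could not satisfy its construction
    guarantee within the bounded retry budget."""
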
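"""Exception types shared across the package."""


class EvtraceError(Exception):
    """Base class for all package errors."""


class FormatError(EvtraceError, ValueError):
    """A file could not be parsed under the documented on-disk conventions."""


class ValidationError(EvtraceError, ValueError):
    """An in-memory object or argument violates a stated invariant."""


class PipelineError(EvtraceError, RuntimeError):
    """A pipeline stage aborted; the message names the stage."""
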
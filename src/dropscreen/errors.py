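"""Exception hierarchy for the pipeline.

Validation errors (bad inputs, mismatched universes) and parameter errors
(impossible settings) are kept distinct from I/O failures so the CLI can map
them to exit codes 2 and 3 respectively.
"""


class DropscreenError(Exception):
    """Base class for all package errors."""


class ValidationError(DropscreenError, ValueError):
    """Input data violates a contract (missing samples, mismatched ids, ...)."""


class ParameterError(DropscreenError, ValueError):
    """A parameter combination is impossible or out of range."""


class PipelineIOError(DropscreenError, IOError):
    """A file could not be read or parsed; names the file and position."""
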
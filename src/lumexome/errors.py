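"""Exception hierarchy shared across the pipeline.

Validation failures (bad values, inconsistent inputs) and format failures
(unparseable files) are distinguished so the CLI can map them to distinct
exit codes.
"""


class LumexomeError(Exception):
    """Base class for all package errors."""


class ValidationError(LumexomeError, ValueError):
    """Input violates a documented precondition or invariant."""


class InvalidConfigError(ValidationError):
    """A configuration object is internally inconsistent."""


class FormatError(LumexomeError, ValueError):
    """A file does not conform to its declared dialect."""


class BuildMismatchError(ValidationError):
    """Genome builds differ where a single build is required."""
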
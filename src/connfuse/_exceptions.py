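"""Exception hierarchy shared across the pipeline.

Validation problems (bad arguments, violated preconditions) are kept
distinct from file-format problems and from numerical failures so that
the command-line layer can map them to stable exit codes.
"""


class ValidationError(ValueError):
    """A precondition on user-supplied data or parameters is violated."""


class FormatError(ValidationError):
    """An on-disk container is missing or has malformed metadata."""


class IntegrityError(ValidationError):
    """Metadata and payload of an on-disk container disagree."""


class NumericalError(RuntimeError):
    """A numerical procedure failed (singular system, unstable fit...)."""
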
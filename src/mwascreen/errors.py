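"""Exception hierarchy for the screening pipeline.

Every stage raises a subclass of :class:`MwasError` so the command-line
driver can attribute a failure to a stage and exit nonzero cleanly.
"""


class MwasError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(MwasError):
    """Malformed or inconsistent input records (names the offenders)."""


class ConfigError(MwasError):
    """Invalid simulation or pipeline configuration."""


class DegenerateDataError(MwasError):
    """A regression cannot be fit because a vector is constant.

    ``kind`` is ``"outcome"`` or ``"exposure"``.
    """

    def __init__(self, kind: str, message: str | None = None):
        self.kind = kind
        super().__init__(message or f"degenerate {kind}: vector is constant")


class AlignmentError(MwasError):
    """Two matrices that must share a row index do not."""
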
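"""Exception hierarchy shared across the package."""


class SSTLabError(Exception):
    """Base class for all package errors."""


class ConfigError(SSTLabError):
    """A session or cohort configuration violates its invariants."""


class ProtocolError(SSTLabError):
    """A task-protocol operation was asked to do something undefined,
    e.g. update the staircase for an unknown stop-stimulus condition."""


class SchemaError(SSTLabError):
    """A trial-log file violates the trial-record schema.

    Carries the offending row number (0-based, excluding the header)
    when one can be identified.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class EstimationUndefinedError(SSTLabError):
    """SSRT estimation is undefined for these data, e.g. the subject
    responded on all stop trials or on none of them."""


class ZeroVarianceError(SSTLabError):
    """A statistic requiring nonzero variance was given constant data."""
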
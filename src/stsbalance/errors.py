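"""Exception hierarchy shared across the package."""


class StsBalanceError(Exception):
    """Base class for all package errors."""


class FormatError(StsBalanceError):
    """A recording file is malformed (missing/ill-typed columns, bad sidecar)."""


class ConsistencyError(StsBalanceError):
    """Metadata and data disagree (e.g. declared vs observed sample rate)."""


class InsufficientDataError(StsBalanceError):
    """Too few samples for the requested operation."""


class ConfigError(StsBalanceError, ValueError):
    """A configuration object violates its invariants."""


class UsageError(StsBalanceError):
    """An operation was applied to the wrong kind of input (e.g. trial type)."""


class DegenerateStatisticError(StsBalanceError):
    """A statistic is undefined for the given inputs (zero SD, empty cohort...)."""
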
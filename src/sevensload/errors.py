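"""Exception types shared across the pipeline.

Exit-code mapping used by the CLI lives in :mod:`sevensload.cli`.
"""


class SevensLoadError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SevensLoadError):
    """Invalid or unresolvable run configuration."""


class ThresholdUnusableError(SevensLoadError, ValueError):
    """A sprint-entry threshold does not exceed the walk/run boundary."""


class SchemaError(SevensLoadError):
    """An input table is missing required columns; names the columns."""


class JoinKeyError(SevensLoadError):
    """A key present in one source is absent from another; names the key."""


class DuplicateRecordError(SevensLoadError):
    """More than one row shares an (athlete, match) pair."""


class EmptyDatasetError(SevensLoadError):
    """Listwise deletion (or a filter) removed every record."""


class CollinearityError(SevensLoadError):
    """The fixed-effects design matrix is rank deficient.

    Carries the offending column names in ``columns``.
    """

    def __init__(self, message: str, columns: list[str] | None = None):
        super().__init__(message)
        self.columns = list(columns or [])


class FitFailedError(SevensLoadError):
    """The mixed-model optimizer did not converge; carries its trace."""

    def __init__(self, message: str, trace: object = None):
        super().__init__(message)
        self.trace = trace


class DegenerateDesignError(SevensLoadError):
    """An ANOVA cell has too few observations to estimate its effect."""


class PairingError(SevensLoadError):
    """Actual/predicted rows cannot be paired; carries orphan keys."""

    def __init__(self, message: str, orphans: list | None = None):
        super().__init__(message)
        self.orphans = list(orphans or [])
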
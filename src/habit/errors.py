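"""Exception hierarchy shared across the package."""


class HabitError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(HabitError, ValueError):
    """An argument violates a documented precondition."""


class ConfigError(HabitError, ValueError):
    """A configuration bundle is internally inconsistent."""


class SchemaError(HabitError):
    """An input table is missing required columns."""


class ParseError(HabitError):
    """Rows of an input table could not be interpreted.

    Carries the offending 1-based line numbers so users can fix the file.
    """

    def __init__(self, message: str, lines: list[int] | None = None):
        super().__init__(message)
        self.lines = lines or []


class ConflictError(HabitError):
    """Duplicate (fly, trial) records in the input."""


class IncompleteSessionError(HabitError):
    """A fly's trial indices do not cover 1..n_trials contiguously."""


class RankDeficientError(HabitError):
    """Design matrix is rank deficient; names the aliased terms."""

    def __init__(self, message: str, aliased: list[str] | None = None):
        super().__init__(message)
        self.aliased = aliased or []


class NoNmjDetectedError(HabitError):
    """Segmentation found no foreground object after filtering."""


class GenerationError(HabitError):
    """A synthetic scene could not be placed within the retry budget."""
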
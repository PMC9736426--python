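"""Exception hierarchy.

Every error raised by the library derives from :class:`NichecastError` so
callers (and the pipeline stage runner) can catch domain failures without
swallowing programming errors.
"""


class NichecastError(Exception):
    """Base class for all nichecast errors."""


class ParameterError(NichecastError, ValueError):
    """An argument is outside its documented domain."""


class SizeError(NichecastError, ValueError):
    """A requested sample size exceeds the eligible population."""


class AlignmentError(NichecastError, ValueError):
    """Grids or layer sets that must share a shape/variable set do not."""


class SchemaError(NichecastError, KeyError):
    """A required variable/column is missing from the input."""


class DegenerateInputError(NichecastError, ValueError):
    """Input is structurally degenerate (e.g. zero-variance variable)."""


class DegenerateHullError(DegenerateInputError):
    """Projected occurrences are collinear; no 2-D hull exists."""


class SplitError(NichecastError, ValueError):
    """A class has too few records for a stratified train/test split."""


class UndefinedAUCError(NichecastError, ValueError):
    """AUC requested with only one class present."""


class FitError(NichecastError, RuntimeError):
    """A model member failed to fit; carries family and replicate id."""

    def __init__(self, family: str, replicate: int, message: str):
        super().__init__(f"{family} replicate {replicate}: {message}")
        self.family = family
        self.replicate = replicate


class EmptyEnsembleError(NichecastError, RuntimeError):
    """No member passed the AUC retention threshold."""


class DegenerateReferenceError(NichecastError, ValueError):
    """Standardization reference has zero spread."""


class MaskError(NichecastError, ValueError):
    """A change-map mask selects no cells."""


class DegenerateTestError(NichecastError, ValueError):
    """Test statistic undefined (e.g. zero-variance paired differences)."""


class LoadError(NichecastError, ValueError):
    """A data file failed validation; message names the file (and row)."""


class ConfigError(NichecastError, ValueError):
    """Run configuration invalid."""


class StageError(NichecastError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
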
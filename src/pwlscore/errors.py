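"""Package-specific exception types.

Every error raised by pwlscore for invalid scientific input derives from
:class:`PwlscoreError`, so callers can distinguish domain validation
failures from programming errors.
"""


class PwlscoreError(ValueError):
    """Base class for domain validation errors."""


class InvalidParameterError(PwlscoreError):
    """A configuration value is outside its scientific domain."""


class DimensionError(PwlscoreError):
    """Array shapes or feature counts do not line up."""


class DegenerateFeatureError(PwlscoreError):
    """A quantitative feature has zero variance on the fitting cohort."""

    def __init__(self, features):
        self.features = list(features)
        super().__init__(
            "zero-variance quantitative feature(s) on the discovery cohort: "
            + ", ".join(map(str, self.features))
        )


class DegenerateLabelError(PwlscoreError):
    """Only one outcome class present; a classifier cannot be fitted."""


class SchemaError(PwlscoreError):
    """A required column/feature is missing or unknown."""


class EmptyModelError(PwlscoreError):
    """Feature extraction produced an empty simple-score model."""


class UndefinedTestError(PwlscoreError):
    """A statistical test is undefined on the given data (e.g. all censored)."""
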
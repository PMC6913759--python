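"""Exception types raised across the pipeline stages."""


class PainvolError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PainvolError):
    """Invalid parameter or configuration value."""


class CohortParseError(PainvolError):
    """A cohort file row is structurally malformed (missing mandatory field)."""


class CohortValidationError(PainvolError):
    """A cohort row is well-formed but violates a domain constraint."""


class UndefinedVolatilityError(PainvolError):
    """Volatility requested for a series with fewer than two ratings."""


class DegenerateFitError(PainvolError):
    """Trend line requested for records without two distinct time points."""


class DegenerateClusteringError(PainvolError):
    """Two-cluster split requested for values with fewer than two distinct points."""


class SchemaMismatchError(PainvolError):
    """Feature matrix columns do not match the schema a model was trained on."""


class StageError(PainvolError):
    """A pipeline stage failed; the message is tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
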
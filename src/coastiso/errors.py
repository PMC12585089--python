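"""Exception types shared across the pipeline."""


class CoastisoError(Exception):
    """Base class for all package-specific errors."""


class EmptyDatasetError(CoastisoError):
    """No records survived parsing or filtering."""


class UnmappedVocabularyError(CoastisoError, KeyError):
    """A raw habit or end-member label is not in the controlled vocabulary."""


class InsufficientDataError(CoastisoError, ValueError):
    """Too few observations for the requested statistic."""


class SingularFitError(CoastisoError, ValueError):
    """Degenerate design (zero-variance predictor or singular scatter)."""


class UnscorableError(CoastisoError, ValueError):
    """All coastscape features unknown; no score can be formed."""


class ConfigurationError(CoastisoError):
    """Inconsistent model bank / genus map / pipeline configuration."""
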
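"""Exception hierarchy shared across the pipeline stages."""


class PDScreenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PDScreenError, ValueError):
    """A file does not follow the expected on-disk layout."""


class SchemaError(PDScreenError, ValueError):
    """A feature table is missing required columns or carries unknown ones."""


class EmptyInputError(PDScreenError, ValueError):
    """A file or signal contained no usable data."""


class ParameterError(PDScreenError, ValueError):
    """An argument is outside its documented domain."""


class InsufficientDataError(PDScreenError, ValueError):
    """The signal is too short for the requested analysis."""


class TooShortError(InsufficientDataError):
    """A phonation does not survive the lead/tail truncation rule."""


class InsufficientVoicingError(InsufficientDataError):
    """Too few voiced cycles were found to compute perturbation measures."""


class DegenerateLabelError(PDScreenError, ValueError):
    """A labelled table holds a single class where at least two are needed."""


class FoldError(PDScreenError, ValueError):
    """Cross-validation folds cannot be formed from the given table."""


class CompositionError(PDScreenError, ValueError):
    """Synthetic patient profiles cannot be assembled from the given tables."""


class ConfigError(PDScreenError, ValueError):
    """A pipeline configuration carries an unknown or invalid key."""
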
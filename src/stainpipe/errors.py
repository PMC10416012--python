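"""Exception hierarchy shared across the toolkit."""


class StainpipeError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(StainpipeError, ValueError):
    """Malformed input data (non-finite pixels, shape mismatch, ...)."""


class ConfigurationError(StainpipeError, ValueError):
    """Inconsistent or unsupported configuration values."""


class InsufficientTissue(StainpipeError):
    """Too few foreground pixels to estimate stain vectors."""


class DegenerateStains(StainpipeError):
    """Stain matrix is (numerically) rank deficient; the two dye
    directions cannot be separated."""


class DegenerateLabels(StainpipeError):
    """A binary task was given single-class labels."""


class NoTiles(StainpipeError):
    """A slide-level score was requested for an empty tile set."""


class UndefinedROC(StainpipeError):
    """ROC/AUC requested with only one class present."""
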
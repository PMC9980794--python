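"""Exception hierarchy shared across the package."""


class MitoscreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MitoscreenError, ValueError):
    """A configuration field is missing, out of range, or inconsistent."""


class GenerationError(MitoscreenError):
    """Synthetic-data generation could not satisfy its geometric constraints."""


class CurationError(MitoscreenError):
    """Training-set curation removed every candidate positive."""


class FingerprintError(MitoscreenError):
    """An entity has no usable text from which to build a fingerprint."""


class RankingError(MitoscreenError):
    """The candidate ranking cannot be computed (e.g. nothing survives filtering)."""


class ValidationError(MitoscreenError):
    """Cross-validation or ROC construction received inconsistent inputs."""


class ScreenError(MitoscreenError):
    """Plate-screen scoring failed (non-separable controls, degenerate spread...)."""


class QuantError(MitoscreenError):
    """Image quantification failed (missing channel, empty mask...)."""
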
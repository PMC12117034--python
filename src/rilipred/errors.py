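"""Exception hierarchy.

Estimator classes raise plain :class:`ValueError` on bad input, following
scikit-learn convention; everything else uses the subclasses below so callers
can distinguish configuration problems from data problems.
"""


class RilipredError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(RilipredError, ValueError):
    """A cohort / phantom configuration is internally inconsistent."""


class SchemaError(RilipredError, ValueError):
    """A feature table is missing required columns or violates invariants."""


class ExtractionError(RilipredError, ValueError):
    """Feature extraction is impossible (empty mask, shape mismatch...)."""


class GenerationError(RilipredError, RuntimeError):
    """A phantom target cannot be realised inside the configured grid."""
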
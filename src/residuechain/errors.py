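"""Exception and warning types shared across the package."""


class ResidueChainError(Exception):
    """Base class for all package errors."""


class ModelLookupError(ResidueChainError, KeyError):
    """Unknown pesticide or matrix requested from the model registry."""


class DesignError(ResidueChainError, ValueError):
    """Invalid study design or scenario grid."""


class ValidationError(ResidueChainError, ValueError):
    """Input data violates a structural invariant."""


class SchemaError(ValidationError):
    """Delimited input is missing a required column."""


class FitError(ResidueChainError, ValueError):
    """Too little usable data to fit a model."""


class RankError(FitError):
    """Design matrix is rank deficient (aliased columns)."""


class NormalizationError(ResidueChainError, ValueError):
    """Day-0 concentration missing or zero when ratios were requested."""


class HorizonError(ResidueChainError, ValueError):
    """Requested horizon lies outside the observed time span."""


class ClampWarning(UserWarning):
    """A surface-model evaluation left [0, 1] and was clamped."""


class KineticsWarning(UserWarning):
    """Non-identifiable or degenerate kinetic fit (e.g. non-positive rate)."""


class CalibrationWarning(UserWarning):
    """Rate-model calibration hit a constraint (e.g. slope clipped to zero)."""
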
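"""Exception types raised across the pipeline.

All inherit ValueError so generic guards still work; the subclasses let
callers distinguish mis-specified inputs (e.g. swapped reference ROIs)
from plain bad arguments.
"""


class SizingError(ValueError):
    """Volume/grid shapes are incompatible or degenerate."""


class DomainError(ValueError):
    """A parameter is outside its physically meaningful domain."""


class ConfigError(ValueError):
    """Pipeline or scanner configuration is inconsistent."""


class ConditioningError(ValueError):
    """Echo configuration makes the fat-water system numerically singular."""


class DegenerateReferenceError(ValueError):
    """Reference fat/water ROIs yield non-separable fat-fraction values."""


class SingularCorrectionError(ValueError):
    """Correction factors collapse (a == b); the bias model is not invertible."""


class PairingError(ValueError):
    """Paired sequences differ in length or keys."""


class RankError(ValueError):
    """Regression design is rank deficient (constant predictor)."""


class InsufficientFoldsError(ValueError):
    """Too few cross-validation units to leave one out."""


class FormatError(ValueError):
    """On-disk data does not match its declared layout or sidecar."""
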
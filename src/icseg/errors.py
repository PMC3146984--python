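"""Exception hierarchy shared across the segmentation pipeline."""


class ICSError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(ICSError, ValueError):
    """An input array or object violates a documented precondition."""


class InvalidParameterError(ICSError, ValueError):
    """A tunable parameter is outside its documented range."""


class SeedPlacementError(ICSError):
    """No valid seed-box placement exists in the required spatial domain."""


class InsufficientTrainingError(ICSError):
    """A class has too few training samples to fit a Gaussian model."""


class EmptyLesionError(ICSError):
    """Segmentation produced no lesion region."""
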
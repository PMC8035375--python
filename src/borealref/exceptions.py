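"""Exception hierarchy shared across the package."""


class BorealRefError(ValueError):
    """Base class for all domain errors raised by this package."""


class InvalidParameterError(BorealRefError):
    """A parameter is outside its valid domain (non-positive interval, bad share, ...)."""


class SchemeMismatchError(BorealRefError):
    """Two age-class distributions were combined but live on different schemes."""


class RebinError(BorealRefError):
    """A re-binning would require information the source bins do not carry."""


class InfeasibleMarginalsError(BorealRefError):
    """Requested matrix marginals leave a negative residual cell."""
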
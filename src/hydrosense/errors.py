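"""Exception hierarchy shared across the pipeline stages."""


class HydrosenseError(Exception):
    """Base class for all package errors."""


class ValidationError(HydrosenseError, ValueError):
    """Invalid user input (bad grids, non-physical parameters, ...)."""


class NoFringesError(HydrosenseError):
    """No periodic etalon modulation detectable in an empty-cell spectrum."""


class InsufficientRangeError(HydrosenseError):
    """Spectral range spans fewer fringe periods than required for a reliable estimate."""


class FitError(HydrosenseError):
    """A model fit failed to converge."""
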
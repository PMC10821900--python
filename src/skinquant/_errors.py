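"""Exception hierarchy shared across the package."""


class SkinQuantError(Exception):
    """Base class for all skinquant errors."""


class ValidationError(SkinQuantError, ValueError):
    """Invalid argument or parameter combination."""


class PlacementError(SkinQuantError):
    """Follicle placement infeasible after bounded retries."""


class FormatError(SkinQuantError):
    """Malformed or inconsistent input file."""


class ConfigError(SkinQuantError):
    """Unknown key or invalid value in a configuration mapping."""


class InsufficientDataError(SkinQuantError):
    """Too few samples (pixels, mice, ...) for the requested fit or test."""


class DegenerateFitError(SkinQuantError):
    """Fit is undefined (e.g. zero predictor variance in the bleed mask)."""


class EmptyDAPIError(SkinQuantError):
    """DAPI foreground is empty; an area ratio is undefined, not zero."""
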
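"""Exception hierarchy.

``CondquantError`` is the base for everything raised on bad data; the CLI
maps it to exit code 2. Usage problems (bad flags) are left to click.
"""


class CondquantError(Exception):
    """Base class for data/processing errors."""


class FormatError(CondquantError):
    """Unreadable or malformed input file."""


class DimensionError(CondquantError):
    """Shape mismatch between rasters that must be co-registered."""


class CorrectionError(CondquantError):
    """FRAP correction impossible (e.g. REF <= BG at some frame)."""


class NormalizationError(CondquantError):
    """Normalization denominator is zero or undefined."""


class FitError(CondquantError):
    """Curve fit failed to converge."""


class PlacementError(CondquantError):
    """Synthetic objects could not be placed without overlap."""


class DegenerateMaskWarning(UserWarning):
    """Every pixel is above threshold; the mask is probably meaningless."""
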
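"""Exception hierarchy for aquaniche."""


class AquanicheError(Exception):
    """Base class for all aquaniche errors."""


class ExtentError(AquanicheError, ValueError):
    """A coordinate or area falls outside the grid extent."""


class FormatError(AquanicheError, ValueError):
    """An input file or raster violates the expected format (e.g. non-WGS84 CRS)."""


class ConfigurationError(AquanicheError, ValueError):
    """Inconsistent configuration (e.g. sea filtering requested without a land mask)."""


class DataError(AquanicheError, ValueError):
    """Input data unusable for the requested computation (too few rows, missing cells)."""


class DegenerateBoundaryError(AquanicheError, RuntimeError):
    """Every Monte-Carlo sample was rejected; the fitted boundary encloses no volume.

    Usually fixed by raising ``gamma`` (tighter kernel) or ``box_margin``.
    """


class AdapterDisabledError(AquanicheError, RuntimeError):
    """A network adapter was invoked without explicitly enabling network access."""
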
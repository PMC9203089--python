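"""Exception hierarchy for biliphone.

All errors derive from :class:`BiliphoneError` so callers can catch the
package's failures with a single except clause; most also derive from
``ValueError`` because they signal invalid inputs.
"""


class BiliphoneError(Exception):
    """Base class for all biliphone errors."""


class InvalidParameterError(BiliphoneError, ValueError):
    """A parameter violates its documented range or invariant."""


class UnsupportedWavelengthError(BiliphoneError, ValueError):
    """A wavelength falls outside the chromophore extinction tables (400-700 nm)."""


class UnsupportedBandError(BiliphoneError, ValueError):
    """A channel passband is not fully covered by the spectral grid."""


class GeometryError(BiliphoneError, ValueError):
    """Adapter geometry is internally inconsistent."""


class DegenerateSimulationError(BiliphoneError, RuntimeError):
    """A simulation collected no photons where a denominator is required."""


class InvalidMosaicError(BiliphoneError, ValueError):
    """Raw frame dimensions or mosaic tag are inconsistent."""


class InsufficientDataError(BiliphoneError, ValueError):
    """Too few frames (or patients) to perform the requested operation."""


class CalibrationError(BiliphoneError, ValueError):
    """Calibration denominator is unusable over the whole field."""


class DegenerateROIError(BiliphoneError, ValueError):
    """An arc ROI does not intersect the field of view."""


class MaskedROIError(BiliphoneError, ValueError):
    """An arc ROI is fully covered by the saturation mask."""


class StratificationError(BiliphoneError, ValueError):
    """A TSB stratum holds too few patients for the requested split."""


class SingularDesignError(BiliphoneError, ValueError):
    """Design matrix is degenerate (collinear) beyond what minimum-norm IRLS tolerates."""


class InvalidResponseError(BiliphoneError, ValueError):
    """Gamma GLM response contains non-positive values."""
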
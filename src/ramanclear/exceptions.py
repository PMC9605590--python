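"""Exception hierarchy.

All errors raised by this package derive from :class:`RamanClearError`
so callers can catch the package's failures with a single ``except``.
"""


class RamanClearError(Exception):
    """Base class for all ramanclear errors."""


class SpectrumParseError(RamanClearError):
    """A spectrum file could not be parsed (message names the line)."""


class SpectrumValidationError(RamanClearError):
    """A spectrum violates a structural invariant (axis, span, metadata)."""


class AxisMismatchError(RamanClearError):
    """Spectra expected to share a wavenumber axis do not."""


class GroupingError(RamanClearError):
    """Spectra expected to share region/depth/time metadata do not."""


class BandWindowError(RamanClearError):
    """A band extraction window does not overlap the spectrum axis."""


class DegenerateFitError(RamanClearError):
    """Too few points for the requested polynomial baseline order."""


class ParameterError(RamanClearError):
    """An invalid preprocessing or fitting parameter."""


class CalibrationError(RamanClearError):
    """Calibration could not be fitted (too few or degenerate standards)."""


class InversionError(RamanClearError):
    """A calibration line with zero slope cannot be inverted."""


class ReferenceIntensityError(RamanClearError):
    """An untreated reference intensity is non-positive."""


class CorrectionError(RamanClearError):
    """A non-positive clearing-efficiency value cannot correct a signal."""


class AlignmentError(RamanClearError):
    """Time axes of series expected to match do not."""


class StabilityError(RamanClearError):
    """An explicit finite-difference grid violates the stability bound."""


class CompletenessError(RamanClearError):
    """A per-depth summary is missing one of the reference bands."""


class CoverageError(RamanClearError):
    """A spectrum does not cover the wavenumber window required by a fit."""


class NormalizationError(RamanClearError):
    """The protein reference area is zero; ratios are undefined."""


class ConfigError(RamanClearError):
    """A pipeline configuration field is invalid (message names the field)."""
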
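"""Exception hierarchy.

Every contract violation raises a distinctly named error so callers (and the
CLI exit-code mapping) can tell configuration mistakes from data problems.
"""


class OxispecError(Exception):
    """Base class for all package errors."""


class ConfigError(OxispecError):
    """Invalid or incomplete run configuration."""


class DataError(OxispecError):
    """Base class for problems with input data."""


class MalformedFileError(DataError):
    """A file does not conform to its documented CSV dialect."""


class GridOrderError(DataError):
    """Wavelengths are not strictly increasing (includes duplicates)."""


class GridRangeError(DataError):
    """A wavelength grid falls outside the admissible/covered range."""


class CoverageError(DataError):
    """A table or spectrum does not cover the required wavelength window."""


class SpectrumValidationError(DataError):
    """A spectrum violates one of its invariants."""


class AlignmentError(DataError):
    """Two spectra/series cannot be brought onto a common grid or time span."""


class NormalizationError(DataError):
    """Spectrum cannot be normalized (no strictly positive value)."""


class NumericDomainError(DataError):
    """A numeric transform was asked outside its domain (e.g. log of <= 0)."""


class UndefinedSaturationError(DataError):
    """StO2 is undefined because both haemoglobin amplitudes are zero."""


class FitPreconditionError(DataError):
    """The absorbance spectrum cannot support the requested fit."""


class PhaseError(DataError):
    """A phase average was requested with data on only one side of the split."""


class ProfileError(DataError):
    """A pump step-down profile has too few or invalid flow levels."""


class ParameterError(OxispecError):
    """An operation parameter is invalid (window size, artifact kind, ...)."""


class InfeasibleTruthError(ParameterError):
    """Simulated truth absorbance exceeds the lamp spectrum somewhere."""
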
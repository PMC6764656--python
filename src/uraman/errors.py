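"""Exception hierarchy.

Every error raised by the library derives from :class:`UramanError`, so
callers (and the CLI) can distinguish bad input data from programming
errors with a single ``except`` clause.
"""


class UramanError(Exception):
    """Base class for all library errors."""


class ParseError(UramanError):
    """A cell in an input file could not be parsed; names row/column."""


class FormatError(UramanError):
    """Structural problem in an input file (duplicate shifts, bad header)."""


class GridRangeError(UramanError):
    """Requested grid extends beyond the source spectrum's shift range."""


class ValidationError(UramanError):
    """Metadata or domain-type invariant violated."""


class DegenerateSpectrumError(UramanError):
    """A spectrum is unusable (e.g. zero-norm row cannot be normalized)."""


class UnderdeterminedFitError(UramanError):
    """Fewer channels than polynomial coefficients in a baseline fit."""


class WindowError(UramanError):
    """Analysis window does not overlap the shift grid."""


class InsufficientDataError(UramanError):
    """Too few rows/observations for the requested operation."""


class CoverageError(UramanError):
    """Requested cumulative variance target is unreachable."""


class DimensionError(UramanError):
    """Shape mismatch between spectra, grids or score vectors."""


class ClassSizeError(UramanError):
    """A class/group has too few members for the requested fit."""


class ConditioningError(UramanError):
    """A covariance matrix is singular even after regularization."""


class FoldDegeneracyError(UramanError):
    """Leave-one-out would leave a fold with a degenerate class."""


class MissingControlError(UramanError):
    """No control rows available where a control reference is required."""


class ConfigError(UramanError):
    """Invalid configuration value."""
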
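"""Exception hierarchy shared across the package."""


class SpectraitsError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SpectraitsError):
    """A file violates the expected layout (header, wavelength order, ...)."""


class ParseError(SpectraitsError):
    """A cell could not be parsed or fails validation; carries row/column."""

    def __init__(self, message, row=None, column=None):
        super().__init__(message)
        self.row = row
        self.column = column


class AlignmentError(SpectraitsError):
    """Two spectra tables do not share the same wavelength grid."""


class DegenerateSpectrumError(SpectraitsError):
    """An operation left the wavelength grid (or dataset) empty."""


class DegenerateLabelingError(SpectraitsError):
    """A dichotomization produced an empty class or a zero trait range."""


class EmptyDatasetError(SpectraitsError):
    """All rows were removed by missing-value / outlier screening."""


class ModelError(SpectraitsError):
    """A model could not be fitted."""


class SchemaError(SpectraitsError):
    """Prediction-time feature set does not match the training schema."""


class ConfigError(SpectraitsError):
    """Invalid benchmark configuration."""
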
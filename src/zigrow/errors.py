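"""Exception hierarchy for zigrow."""


class ZigrowError(Exception):
    """Base class for all zigrow errors."""


class SchemaError(ZigrowError):
    """An input table is missing required columns or has malformed values."""


class ReferentialError(ZigrowError):
    """An observation references a genotype or garden that does not exist."""


class DuplicateRowError(ZigrowError):
    """Duplicate (individual_id, year) rows indicate corrupted input."""


class DegenerateInputError(ZigrowError):
    """An input is structurally valid but numerically degenerate."""


class DimensionError(ZigrowError):
    """Requested dimensions exceed what the data supports."""


class InsufficientDataError(ZigrowError):
    """Too few records remain to compute the requested statistic."""


class ConfigurationError(ZigrowError):
    """A model or simulation configuration is internally inconsistent."""


class RankDeficiencyError(ZigrowError):
    """The fixed-effect design matrix is singular."""

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = list(columns)


class InnerConvergenceError(ZigrowError):
    """The inner Newton solver for random-effect modes failed to converge."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SizeGuardError(ZigrowError):
    """A brute-force oracle was asked for an instance beyond its cost guard."""


class AlignmentError(ZigrowError):
    """Two rasters or result tables do not share shape/keys."""


class FormatError(ZigrowError):
    """A raster file is not in a supported single-band format."""


class PairingError(ZigrowError):
    """Paired comparison requested on results with no shared keys."""
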
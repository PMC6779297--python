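"""Exception hierarchy shared across the package."""


class CellFishingError(Exception):
    """Base class for all domain errors raised by this package."""


class InvalidStructureError(CellFishingError):
    """A SMILES string could not be parsed into a molecule."""


class FormatError(CellFishingError):
    """An input file is structurally unusable (e.g. a required column is missing)."""


class UnitError(CellFishingError):
    """A concentration unit string is not recognized."""


class DimensionError(CellFishingError):
    """Fingerprint lengths or matrix shapes are incompatible."""


class NoReferenceError(CellFishingError):
    """A cell line has no sensitive reference compounds to compare against."""


class ConfigurationError(CellFishingError):
    """Two model components disagree on the cell-line space or other settings."""


class TrainingError(CellFishingError):
    """A classifier cannot be trained on the supplied data (e.g. single class)."""


class LeakageError(CellFishingError):
    """External-validation queries overlap the reference database."""
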
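"""Exception hierarchy for the wheatlwc pipeline."""


class WheatLwcError(Exception):
    """Base class for all wheatlwc errors."""


class SpectraFormatError(WheatLwcError):
    """A spectra CSV is structurally malformed (missing/duplicated columns)."""


class SpectraValidationError(WheatLwcError):
    """Spectra values violate an invariant (e.g. reflectance outside [0, 1])."""


class MissingBandError(WheatLwcError, KeyError):
    """A requested wavelength is not on the (possibly masked) grid."""


class DegenerateInputError(WheatLwcError):
    """An operation would produce an empty or meaningless result."""


class EmptyResultError(WheatLwcError):
    """A search produced no defined cells to rank."""


class InsufficientDataError(WheatLwcError):
    """Too few samples for the requested statistic or fit."""


class CatalogError(WheatLwcError, KeyError):
    """Unknown spectral-index name."""


class ConfigurationError(WheatLwcError):
    """A configuration is internally inconsistent or physically implausible."""


class DomainError(WheatLwcError, ValueError):
    """An argument lies outside the mathematical domain of the operation."""
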
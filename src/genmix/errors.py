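"""Exception types shared across the package."""


class GenmixError(Exception):
    """Base class for all package errors."""


class PedigreeError(GenmixError):
    """Malformed pedigree: cycles, duplicate ids, or ordering violations."""


class DataError(GenmixError):
    """Inconsistent or malformed input data (haplotypes, phenotypes, ids)."""


class FitError(GenmixError):
    """A model fit could not be performed (singular design, non-PSD kinship)."""
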
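"""Exception hierarchy for lipidmr.

Every error raised on a contract violation derives from :class:`LipidMrError`
so callers can catch package errors without masking programming mistakes.
"""


class LipidMrError(Exception):
    """Base class for all lipidmr errors."""


class FormatError(LipidMrError):
    """A summary-statistics file does not match the declared dialect."""


class ValidationError(LipidMrError):
    """Input records violate a domain invariant (e.g. duplicate SNP ids)."""


class EmptyResultError(LipidMrError):
    """An operation that requires a non-empty table produced or received none."""


class DegenerateTableError(LipidMrError):
    """A table is structurally valid but unusable (e.g. zero maximum sample size)."""


class CoordinateError(LipidMrError):
    """Genomic coordinates required for distance pruning are missing."""


class HarmonizationError(LipidMrError):
    """Allele labels cannot be reconciled between an exposure and the outcome."""


class ClassificationError(LipidMrError):
    """A SNP reached the pleiotropy partition with no exposure membership."""


class InsufficientInstrumentsError(LipidMrError):
    """Fewer instruments than the estimator's minimum."""


class CollinearityError(LipidMrError):
    """Rank-deficient design matrix in a multivariable fit."""


class UndefinedStatisticError(LipidMrError):
    """A statistic has no finite value for the given input (e.g. SE from p=1)."""


class CapacityError(LipidMrError):
    """The null background cannot absorb the requested embedding."""


class ConfigError(LipidMrError):
    """Inconsistent configuration values."""
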
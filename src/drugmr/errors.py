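"""Exception hierarchy.

Every error raised by drugmr derives from :class:`DrugMRError`, so callers
(notably the pipeline driver) can distinguish analysis-level failures from
programming errors.
"""


class DrugMRError(Exception):
    """Base class for all drugmr errors."""


class SchemaError(DrugMRError):
    """Input table is missing a mandatory column or contains an unknown token."""


class EmptyInputError(DrugMRError):
    """An operation received an empty file or empty result set."""


class CoordinateError(DrugMRError):
    """Genomic interval is malformed (e.g. start > end)."""


class MatrixError(DrugMRError):
    """LD matrix is not square/symmetric or contains out-of-range values."""


class DomainError(DrugMRError):
    """A numeric argument lies outside its mathematically valid domain."""


class NoOverlapError(DrugMRError):
    """Exposure and outcome summary statistics share no variants."""


class DuplicateVariantError(SchemaError):
    """The same variant identifier appears more than once."""


class InsufficientInstrumentsError(DrugMRError):
    """Fewer instruments survived selection/filtering than the method needs.

    Carries ``n_selected`` so the pipeline can report how many survived
    before skipping the gene.
    """

    def __init__(self, message: str, n_selected: int = 0):
        super().__init__(message)
        self.n_selected = n_selected


class ZeroExposureEffectError(DrugMRError):
    """A Wald ratio is undefined because the exposure effect is exactly zero."""


class CollinearityError(DrugMRError):
    """Regression design is degenerate (no variance in the exposure effects)."""


class SampleSizeError(DrugMRError):
    """Per-SNP sample size too small for the requested statistic."""


class ConvergenceError(DrugMRError):
    """Iterative optimisation failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class ScaleMismatchError(DrugMRError):
    """Estimates on different scales (beta vs log-OR) cannot be pooled."""


class ConfigError(DrugMRError):
    """Invalid configuration value or combination."""
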
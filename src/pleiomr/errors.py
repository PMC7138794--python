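"""Exception hierarchy shared across the package."""


class PleiomrError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PleiomrError):
    """A required option, column mapping, or scenario setting is invalid."""


class EmptyInputError(PleiomrError):
    """A summary-statistics source yielded no valid rows."""


class EmptyInstrumentError(PleiomrError):
    """No SNP survived selection/harmonization; nothing to estimate with."""


class InsufficientSnpsError(PleiomrError):
    """An estimator or diagnostic needs more SNPs than the set contains."""


class DivisionError(PleiomrError):
    """A Wald ratio is undefined because a SNP-exposure effect is zero."""


class CollinearityError(PleiomrError):
    """The multivariable exposure-effect matrix is rank deficient."""


class DegreesOfFreedomError(PleiomrError):
    """Sample size too small for the requested instrument-strength statistic."""
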
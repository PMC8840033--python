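"""Exception types shared across the package."""


class LeaktrajError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LeaktrajError, ValueError):
    """A configuration object is internally inconsistent or incomplete."""


class InsufficientDataError(LeaktrajError, ValueError):
    """Too few observations to compute the requested statistic."""


class DegenerateDesignError(LeaktrajError, ValueError):
    """The design matrix carries no information (e.g. all days identical)."""


class SingleClassError(LeaktrajError, ValueError):
    """Both outcome classes are required but only one is present."""
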
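"""Exception hierarchy shared across the pipeline stages."""


class OtosignalError(Exception):
    """Base class for all errors raised by otosignal."""


class FormatError(OtosignalError):
    """An input file does not match its declared table dialect."""


class ConsistencyError(OtosignalError):
    """Rows that should agree (same report_id) carry conflicting values."""


class ConfigurationError(OtosignalError):
    """A case definition, group mapping, or config file is invalid."""


class ValidationError(OtosignalError):
    """A generator or pipeline configuration failed validation."""


class DegenerateTableError(OtosignalError):
    """A contingency table has a zero cell (or zero expected count) where
    the requested method cannot proceed."""


class DegenerateInputError(OtosignalError):
    """A sample is too small or has zero variance for the requested test."""


class InsufficientDataError(OtosignalError):
    """No usable rows remain after applying the missing-data policy."""


class SeparationError(OtosignalError):
    """Exposure perfectly predicts case status; the logistic MLE diverges."""


class ConvergenceError(OtosignalError):
    """The iterative model fit did not converge within the iteration cap."""
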
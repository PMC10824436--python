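"""Exception hierarchy shared across the package."""


class PFTError(Exception):
    """Base class for all errors raised by pftinterp."""


class ValidationError(PFTError, ValueError):
    """Input data violates a documented invariant (bad ratio, non-monotone volume, ...)."""


class ParseError(PFTError, ValueError):
    """A file could not be parsed; the message names the offending row/column."""


class DegenerateCurveError(PFTError):
    """A flow-volume curve has no usable descending limb or collapsed landmarks."""


class InsufficientDataError(PFTError):
    """Too few points/values for the requested computation."""


class UnsupportedDocumentError(PFTError):
    """A PDF report lacks a machine-readable text layer."""


class MissingDependencyError(PFTError, ImportError):
    """An optional dependency required for this entry point is not installed."""


class UndefinedKappaError(PFTError):
    """Cohen's kappa is undefined because chance agreement equals 1 (degenerate marginals)."""
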
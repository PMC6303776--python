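"""Exception types shared across the package."""


class NursepartError(Exception):
    """Base class for all package errors."""


class FormatError(NursepartError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(NursepartError):
    """Data violate an invariant (negative counts, duplicate ids, ...)."""


class FitError(NursepartError):
    """A model fit failed or did not converge."""
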
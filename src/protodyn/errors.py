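"""Exception hierarchy shared across the pipeline."""


class ProtodynError(Exception):
    """Base class for all package errors."""


class InputError(ProtodynError, ValueError):
    """Malformed or inconsistent user input (grids, pairing, signs)."""


class DomainError(ProtodynError, ValueError):
    """Argument outside the validity window of a physical model."""


class DegenerateInputError(ProtodynError, ValueError):
    """Structurally valid input on which the requested statistic is undefined
    (e.g. a flat curve has no peak)."""


class AnalysisError(ProtodynError, RuntimeError):
    """A fit or detection step failed to converge or to find its target."""


class IdentifiabilityError(AnalysisError):
    """The requested parameters cannot be estimated from the supplied data."""
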
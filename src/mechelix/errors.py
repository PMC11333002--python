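"""Exception hierarchy."""


class MechelixError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(MechelixError, ValueError):
    """An argument violates a documented precondition."""


class MissingAtomError(MechelixError):
    """A required backbone atom (amide H, carbonyl O) is absent."""


class ParseError(MechelixError):
    """A file or state string could not be parsed."""


class EmptyAnalysisError(MechelixError):
    """No frames remain after burn-in removal; refusing to report silent zeros."""


class ConfigurationError(MechelixError):
    """A protocol or integrator configuration is inconsistent or unstable."""


class InsufficientTraceError(MechelixError):
    """A force-extension trace never reaches the requested extension range."""


class DisconnectedHistogramError(MechelixError):
    """Neighboring umbrella windows have no overlapping support."""


class AlignmentError(MechelixError):
    """Free-energy profiles cannot be aligned (grid or anchor mismatch)."""
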
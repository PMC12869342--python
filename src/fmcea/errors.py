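"""Exception hierarchy shared across the package."""


class FMCEAError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FMCEAError, ValueError):
    """An input violated a structural invariant (row sums, ranges, schema)."""


class InfeasibleMomentsError(FMCEAError, ValueError):
    """Requested mean/SE cannot be matched by the requested distribution family."""


class UndefinedICERError(FMCEAError, ZeroDivisionError):
    """ICER requested for a pair with equal effectiveness; handle via dominance."""
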
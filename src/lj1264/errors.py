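"""Exception hierarchy.

All package errors derive from :class:`LJ1264Error` so callers can catch one
base class; the leaf classes mirror the distinct failure contracts (domain
violations, broken call contracts, missing parameters, fitting failures,
solver non-convergence, malformed files, sampler aborts).
"""


class LJ1264Error(Exception):
    """Base class for all package errors."""


class DomainError(LJ1264Error, ValueError):
    """An argument is outside its mathematical/physical domain (e.g. r <= 0)."""


class ContractError(LJ1264Error, ValueError):
    """A call contract between operations was violated (e.g. length mismatch)."""


class ConfigurationError(LJ1264Error, KeyError):
    """A required parameter (e.g. a pair entry) is missing from a table."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return self.args[0] if self.args else ""


class BracketingError(LJ1264Error, ValueError):
    """A root/fit bracket does not straddle the target, or is non-monotone."""


class ToleranceError(LJ1264Error, RuntimeError):
    """A fit could not reach the requested tolerance; carries the best achieved."""

    def __init__(self, message: str, achieved: float | None = None):
        super().__init__(message)
        self.achieved = achieved


class ConvergenceError(LJ1264Error, RuntimeError):
    """An iterative solver hit its iteration cap; carries the residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class FormatError(LJ1264Error, ValueError):
    """A file does not conform to its declared format."""


class SamplerError(LJ1264Error, RuntimeError):
    """The Monte Carlo sampler encountered a non-finite energy."""
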
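"""Exception hierarchy shared across the package."""


class AstrocaError(Exception):
    """Base class for all errors raised by astroca."""


class ValidationError(AstrocaError):
    """Invalid parameters, protocol or configuration (CLI exit code 2)."""


class DomainError(ValidationError):
    """An operation received an input outside its mathematical domain."""


class SolverError(AstrocaError):
    """The reference integrator failed; the message names the failing time."""
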
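"""Exception hierarchy."""


class ActiveDropError(Exception):
    """Base class for all package-specific errors."""


class RegimeError(ActiveDropError):
    """The requested evaluation lies in the high-activity regime (alpha >= r0/2),
    where the interface-localized perturbation analysis is not valid."""


class DomainError(ActiveDropError, ValueError):
    """An argument lies outside the mathematical domain of a function
    (e.g. the pole of a closed form, a negative mode index)."""


class ConvergenceError(ActiveDropError):
    """A root bracket or quadrature failed to converge; distinct from a
    legitimate non-existence result (which is reported as ``None``)."""


class ModeCapError(ActiveDropError):
    """The dominant-mode search hit its mode-index cap, so the reported
    argmax may not be the true maximum."""
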
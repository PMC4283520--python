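"""Exception hierarchy shared across the package."""


class EmforceError(Exception):
    """Base class for all package-specific errors."""


class NetworkFormatError(EmforceError):
    """A network / table file could not be parsed."""


class ValidationError(EmforceError):
    """A constructed object violates a structural invariant."""


class BalanceError(ValidationError):
    """A flux distribution does not satisfy steady-state mass balance."""


class AnchoringError(EmforceError):
    """Elementary rate constants cannot be anchored at the reference state."""


class InfeasibleError(EmforceError):
    """An optimization problem has no feasible point."""


class UnboundedError(EmforceError):
    """An optimization problem is unbounded."""


class ConvergenceError(EmforceError):
    """A nonlinear solve failed to converge."""


class ConfigError(EmforceError):
    """A pipeline configuration file is invalid."""
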
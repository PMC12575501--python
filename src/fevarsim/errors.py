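"""Exception and warning types shared across the package."""


class InvalidConfigError(ValueError):
    """A configuration or generator parameter is outside its valid range."""


class InvalidInputError(ValueError):
    """An input object (centerline, point set, ...) violates a precondition."""


class DeploymentInfeasibleError(ValueError):
    """The requested stent-graft does not fit on the target branch."""


class OutOfValidityError(ValueError):
    """A model was asked to operate outside its validated regime."""


class NonConvergenceError(RuntimeError):
    """The equilibrium solver failed to converge.

    Carries the last iterate so callers can inspect the near-solution.
    """

    def __init__(self, message, last_positions=None, grad_norm=None):
        super().__init__(message)
        self.last_positions = last_positions
        self.grad_norm = grad_norm


class InvalidPairingError(ValueError):
    """Two metric sets that do not belong to the same branch/configuration."""


class MissingArtifactError(FileNotFoundError):
    """A pipeline stage input is absent; names the subcommand that produces it."""


class SelfIntersectionWarning(UserWarning):
    """Tube sweep radius exceeds the local centerline curvature radius."""


class ShortBranchWarning(UserWarning):
    """A generated branch is shorter than some catalog stent-grafts."""
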
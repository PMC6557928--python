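"""Exception hierarchy shared across the package."""


class SrcmError(Exception):
    """Base class for all package errors."""


class ParameterDomainError(SrcmError, ValueError):
    """A kinetic constant or concentration is outside its admissible domain."""


class StructuralError(SrcmError, ValueError):
    """The network refers to undeclared entities or breaks a structural rule."""


class ConfigurationError(SrcmError, ValueError):
    """Inputs are well-formed but inconsistent with the requested operation."""


class SimulationError(SrcmError, RuntimeError):
    """The integrator failed; carries the last time reached when known."""

    def __init__(self, message, last_time=None):
        super().__init__(message)
        self.last_time = last_time


class ConvergenceError(SrcmError, RuntimeError):
    """An iterative solver exhausted its budget; carries the best residual."""

    def __init__(self, message, best_residual=None):
        super().__init__(message)
        self.best_residual = best_residual


class SingularityError(SrcmError, ArithmeticError):
    """A rate law was evaluated at a mathematical singularity."""


class SbmlError(SrcmError, ValueError):
    """SBML document cannot be parsed or expressed by this package."""


class UnsupportedConstructError(SbmlError):
    """A kinetic law or construct falls outside the supported MM/GMA subset."""
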
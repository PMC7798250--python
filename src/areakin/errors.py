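"""Exception hierarchy shared across the package."""


class AreakinError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(AreakinError, ValueError):
    """Invalid shape parameters or inconsistent compartment geometry."""


class ModelError(AreakinError, ValueError):
    """Structurally invalid model (unresolved references, bad constants...)."""


class ConfigurationError(ModelError):
    """A reaction/mode configuration that cannot be resolved against the
    model geometry (e.g. an area-scaled reaction naming a missing interface)."""


class IntegrationError(AreakinError, RuntimeError):
    """The ODE solver failed; carries the solver diagnostics."""


class NotEquilibratedError(AreakinError, RuntimeError):
    """A trajectory did not settle; equilibrium metrics would be meaningless."""


class SteadyStateError(AreakinError, RuntimeError):
    """No steady state found within the allotted integration/Newton budget."""


class CalibrationError(AreakinError, RuntimeError):
    """Cross-implementation calibration failed its identity check."""


class SensitivityError(AreakinError, RuntimeError):
    """A perturbed model could not be solved during sensitivity analysis."""


class SBMLReadError(AreakinError, ValueError):
    """Malformed SBML input."""


class UnsupportedFeatureError(AreakinError, ValueError):
    """SBML constructs outside the supported subset; lists the offenders."""

    def __init__(self, features):
        self.features = tuple(features)
        super().__init__(
            "unsupported SBML construct(s): " + ", ".join(self.features)
        )


class NotRescalableError(AreakinError, ValueError):
    """A kinetic law whose structure does not factor as volume x expression.

    Raised instead of silently guessing how to rewrite a law."""
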
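"""Exception hierarchy.

All package-specific failures derive from :class:`RedoxFermError` so that
callers (and the CLI) can map them onto exit codes without matching on
message text.
"""


class RedoxFermError(Exception):
    """Base class for all errors raised by redoxferm."""


# --- configuration / input declaration -------------------------------------

class ConfigurationError(RedoxFermError):
    """A config file or option set is malformed or internally inconsistent."""


class InvalidFormulaError(ConfigurationError, ValueError):
    """An elemental formula is empty or has negative element counts."""


class UnknownCompoundError(ConfigurationError, KeyError):
    """A reaction references a compound the registry does not know."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0] if self.args else ""


# --- data / measurement tables ---------------------------------------------

class ParseError(RedoxFermError):
    """A measurement table violates the expected schema."""


class DomainError(RedoxFermError, ValueError):
    """A numeric argument lies outside the operation's domain."""


class InsufficientDataError(RedoxFermError):
    """Too few observations for the requested estimate."""


class DegenerateRegressionError(RedoxFermError):
    """The regressor has no variation (e.g. no substrate was consumed)."""


class CalibrationError(RedoxFermError):
    """Observed quantities do not admit a valid parameter calibration."""


# --- stoichiometric infeasibility ------------------------------------------

class InfeasibleCombinationError(RedoxFermError):
    """No non-negative weights can zero the balanced species."""


class AmbiguousCombinationError(RedoxFermError):
    """More than one independent redox-neutral combination exists.

    ``free_directions`` holds a basis of the weight-space nullspace so the
    caller can see the unresolved degrees of freedom.
    """

    def __init__(self, message: str, free_directions=None):
        super().__init__(message)
        self.free_directions = free_directions or []


class InvalidScalingError(RedoxFermError, ValueError):
    """Requested normalization compound is absent or not consumed."""


class InfeasibleBiomassError(RedoxFermError):
    """Biomass parameters force a negative substrate or CO2 coefficient."""


class ModelStructureError(RedoxFermError):
    """The network solve is singular (mis-specified balances)."""


class InfeasibleModelError(RedoxFermError):
    """The network solve requires a negative flux at this growth rate."""


class SimulationIntegrityError(RedoxFermError):
    """A simulated trajectory left the physically meaningful region."""
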
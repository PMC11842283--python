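"""Exception hierarchy shared across the toolkit."""


class SightkitError(Exception):
    """Base class for all sightkit errors."""


class DomainError(SightkitError, ValueError):
    """An input value lies outside the physically meaningful domain."""


class UnknownCompoundError(SightkitError, KeyError):
    """Compound name not found in the registry."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return self.args[0] if self.args else ""


class SaturationError(DomainError):
    """Requested aqueous concentration exceeds the solubility limit."""


class StepSizeError(DomainError):
    """Simulation time step too large for a stable explicit update."""


class LayoutError(SightkitError, ValueError):
    """Invalid plate layout (bad well id, duplicate well, too many wells)."""


class DegenerateFitError(SightkitError, ValueError):
    """Calibration input has no spread; a line cannot be fitted."""


class RangeError(SightkitError, ValueError):
    """Requested evaluation times fall outside the observed curve."""


class ConfigError(SightkitError, ValueError):
    """Run configuration failed validation."""
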
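"""Exception types shared across the package."""


class IonRbeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(IonRbeError):
    """Invalid model configuration (geometry, karyotype, recipe, ...)."""


class UndefinedThresholdError(IonRbeError):
    """Rejoining threshold requested for a configuration with no adjacent territories."""


class OutOfNucleusError(IonRbeError):
    """A point was queried outside the nucleus volume."""


class WrongRadiationKindError(IonRbeError):
    """An operation received a radiation quality of the wrong kind."""


class MissingSpeciesError(IonRbeError):
    """A particle species required by a spectrum is absent from the radiobiological table."""


class DegenerateFitError(IonRbeError):
    """Survival data carry no dose response; the LQ fit is degenerate."""


class CalibrationError(IonRbeError):
    """A calibration search failed to bracket or converge."""
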
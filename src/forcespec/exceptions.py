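"""Package-wide exception types, keyed to pipeline stages."""


class ForcespecError(Exception):
    """Base class for all package errors."""


class ConfigError(ForcespecError):
    """Invalid or incomplete run configuration."""


class MalformedCurveError(ForcespecError):
    """Force-distance record that cannot be segmented."""


class InsufficientBaselineError(ForcespecError):
    """Retract segment too short to estimate a noise baseline."""


class InsufficientDataError(ForcespecError):
    """Not enough events/samples for the requested inference."""


class ConvergenceError(ForcespecError):
    """Iterative fit or solver failed to converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class WindowOverlapError(ForcespecError):
    """Adjacent umbrella windows share no occupied histogram bins."""


class NoBoundStateError(ForcespecError):
    """Free-energy profile has no identifiable bound well."""


class ReferencingError(ForcespecError):
    """Height map background has no dominant bilayer level."""


class PlacementError(ForcespecError):
    """Synthetic map cannot place particles without forced overlap."""
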
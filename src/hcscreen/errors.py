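"""Exception hierarchy for hcscreen."""


class HcsError(Exception):
    """Base class for all hcscreen errors."""


class CapacityError(HcsError, ValueError):
    """Requested wells exceed the plate format capacity."""


class PlacementError(HcsError, RuntimeError):
    """Cells could not be placed without overlap within the retry budget."""


class ConfigurationError(HcsError, ValueError):
    """Inconsistent or incomplete simulation/analysis configuration."""


class DegenerateSeparationError(HcsError, ValueError):
    """Control groups cannot be separated (e.g. equal medians)."""


class DegenerateControlsError(HcsError, ValueError):
    """Negative controls have zero spread or too few wells for z-scoring."""


class EmptyMaskError(HcsError, ValueError):
    """Shape descriptors requested for an empty region."""


class ManifestVersionError(HcsError, ValueError):
    """Cell records carry a feature manifest incompatible with this build."""


class EmptySummaryError(HcsError, ValueError):
    """Summary requested over an empty set (e.g. no converged fits)."""


class CascadeConsistencyError(HcsError, ValueError):
    """Stage inputs do not match the survivors of the previous stage."""
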
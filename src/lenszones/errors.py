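"""Exception types shared across the pipeline."""


class LensZonesError(Exception):
    """Base class for all package errors."""


class ValidationError(LensZonesError):
    """A model, phantom or configuration value violates an invariant."""


class SegmentationError(LensZonesError):
    """An interface or zone could not be segmented; names what is missing."""


class TotalInternalReflection(LensZonesError):
    """Snell refraction has no real solution for at least one ray."""


class CorrectionError(LensZonesError):
    """Refraction correction could not be completed."""
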
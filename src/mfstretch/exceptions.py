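"""Exception types shared across the pipeline."""


class MFStretchError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MFStretchError, ValueError):
    """A physical parameter is outside its admissible range."""


class InvalidGeometryError(MFStretchError, ValueError):
    """Aggregate geometry too small or inconsistent to realise."""


class InvalidConfigurationError(MFStretchError, ValueError):
    """Run configuration is unusable (e.g. field of view too small)."""


class TrackingError(MFStretchError, RuntimeError):
    """Template tracking failed quality control."""


class NoAggregateError(MFStretchError, RuntimeError):
    """Silhouette segmentation found no aggregate in the frame."""


class InsufficientDataError(MFStretchError, ValueError):
    """Too few data points for the requested fit."""


class InvalidInputError(MFStretchError, ValueError):
    """Degenerate statistical input (empty or zero-variance sample)."""


class PairingError(MFStretchError, ValueError):
    """Same-mouse pairing impossible (no shared mice between groups)."""
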
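"""Exception types shared across the package."""


class EapclustError(Exception):
    """Base class for package errors."""


class DegenerateInputError(EapclustError, ValueError):
    """Raised when an input is flat, empty, or otherwise carries no signal."""


class FeatureUndefinedError(EapclustError, ValueError):
    """Raised when a waveform feature does not exist (e.g. no post-trough peak)."""


class BoundaryError(EapclustError, ValueError):
    """Raised when a channel/window sits too close to the probe edge."""


class ParameterError(EapclustError, ValueError):
    """Raised for invalid generator or analysis parameters."""


class TopologyError(EapclustError, ValueError):
    """Raised for malformed morphology trees (cycles, orphans, multiple roots)."""


class InsufficientDataError(EapclustError, ValueError):
    """Raised when a statistical operation has too few samples per class."""


class SchemaError(EapclustError, ValueError):
    """Raised when feature columns do not match the fitted model."""
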
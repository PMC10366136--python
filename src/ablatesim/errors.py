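"""Exception types shared across the simulator."""


class AblateSimError(Exception):
    """Base class for all ablatesim errors."""


class ConfigurationError(AblateSimError, ValueError):
    """A scenario/configuration value is inconsistent or out of range."""


class DomainError(AblateSimError, ValueError):
    """A physical quantity was outside its admissible domain."""


class ConsistencyError(AblateSimError, RuntimeError):
    """An internal invariant was violated (e.g. a missed voxel removal)."""
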
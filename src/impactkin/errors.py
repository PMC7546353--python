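"""Exception types shared across impactkin modules."""


class ImpactKinError(Exception):
    """Base class for all impactkin errors."""


class ConfigError(ImpactKinError, ValueError):
    """Invalid generator or model configuration."""


class FormatError(ImpactKinError, ValueError):
    """Malformed trace file or manifest."""


class DatasetValidationError(ImpactKinError, ValueError):
    """Dataset violates an invariant (duplicate ids, ragged channels, ...)."""


class NoPulseError(ImpactKinError, ValueError):
    """A trace contains no detectable pulse (e.g. identically zero)."""


class DegenerateDataWarning(UserWarning):
    """Statistic computed on degenerate input (e.g. fully tied ranks)."""
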
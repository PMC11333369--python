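"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration object violates its schema or invariants."""


class DomainError(ValueError):
    """An input is outside the physical or mathematical domain of an operation."""


class InfeasibleError(RuntimeError):
    """The moment-balance constraint cannot be met by the available torque sources."""

    def __init__(self, message: str, phase: float | None = None):
        super().__init__(message)
        self.phase = phase


class FormatError(ValueError):
    """A data file does not conform to the documented on-disk format."""


class MetricError(ValueError):
    """An evaluation metric is undefined for the given inputs."""
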
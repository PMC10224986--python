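"""Exception hierarchy for iscmetrics."""


class ISCMetricsError(Exception):
    """Base class for all iscmetrics errors."""


class DimensionError(ISCMetricsError, ValueError):
    """Two arrays that must share a shape do not."""


class UndefinedMetricError(ISCMetricsError, ValueError):
    """A metric is requested for an input on which it is mathematically undefined."""


class ConfigurationError(ISCMetricsError, ValueError):
    """A parameter value breaks a guarantee the caller relies on."""


class CapacityError(ISCMetricsError, RuntimeError):
    """A synthetic scene cannot hold the requested number of instances."""


class FormatError(ISCMetricsError, ValueError):
    """An input file does not conform to the expected label-map format."""
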
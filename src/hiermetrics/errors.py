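"""Exception hierarchy shared by all modules."""


class HiermetricsError(ValueError):
    """Base class for all package-specific errors."""


class SchemaError(HiermetricsError):
    """Invalid or inconsistent input data (bad labels, malformed files,
    mismatched identifiers, non-canonical weight matrices...)."""


class DegenerateMetricError(HiermetricsError):
    """A metric is mathematically undefined for this input, e.g. a
    single-type reference for wNMI or weights with S*(R,R) = 0."""
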
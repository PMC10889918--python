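"""Exception hierarchy for the hypoburden package."""


class HypoburdenError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(HypoburdenError):
    """An input table is missing required columns."""


class ParseError(HypoburdenError):
    """A cell could not be parsed (non-numeric MAP/time, bad boolean)."""


class ValidationError(HypoburdenError):
    """Parsed data violate a model invariant (duplicates, bounds, order)."""


class ConfigError(HypoburdenError):
    """A configuration object is internally inconsistent or infeasible."""


class RoutingError(HypoburdenError):
    """Two-group test routing is impossible (e.g. too few values)."""
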
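"""Exception hierarchy shared across the package."""


class PactCostError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PactCostError):
    """Invalid configuration (arm sizes, perspectives, schedule rules...)."""


class CalibrationError(PactCostError):
    """A calibration target cannot be met by the available items."""


class CostingError(PactCostError):
    """A resource-use record cannot be priced (e.g. unknown item id)."""


class ParseError(PactCostError):
    """Malformed input file; the message names the offending row/field."""
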
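"""Exception hierarchy for metpanel."""


class MetpanelError(Exception):
    """Base class for all metpanel errors."""


class ConfigurationError(MetpanelError):
    """Invalid simulation / pipeline configuration."""


class DataValidationError(MetpanelError):
    """Malformed input table (missing columns, duplicate ids, bad numerics)."""


class InconsistencyError(MetpanelError):
    """Published summary numbers do not round-trip to an integer confusion matrix."""
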
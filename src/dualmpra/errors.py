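"""Exception hierarchy shared across the pipeline stages."""


class DualMPRAError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(DualMPRAError):
    """A configuration value is invalid.

    Carries the offending field name so CLI error messages can point at it.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"config field '{field}': {message}")


class InputError(DualMPRAError):
    """Malformed input data (mixed barcode lengths, missing columns, ...)."""


class StateError(DualMPRAError):
    """An operation was invoked before its prerequisites exist
    (empty catalog, missing ground truth, too few usable controls, ...)."""
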
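"""Exception hierarchy shared across the package."""


class SizescaleError(Exception):
    """Base class for all sizescale-specific errors."""


class ConfigurationError(SizescaleError, ValueError):
    """A configuration object or preset name is invalid."""


class InputError(SizescaleError, ValueError):
    """Arguments violate an operation's preconditions."""


class DomainError(SizescaleError, ValueError):
    """Numeric inputs are outside the mathematical domain of an operation."""


class SchemaError(SizescaleError, ValueError):
    """A table is missing required columns; the message lists the absentees."""

    def __init__(self, missing, context=""):
        self.missing = tuple(missing)
        msg = f"missing required columns: {', '.join(self.missing)}"
        if context:
            msg = f"{context}: {msg}"
        super().__init__(msg)


class ValidationError(SizescaleError, ValueError):
    """Column values violate a documented invariant (e.g. NF outside [0, 1])."""
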
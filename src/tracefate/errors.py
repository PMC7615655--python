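"""Exception hierarchy."""


class TracefateError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TracefateError):
    """Invalid preset name or contradictory build options."""


class ContractError(TracefateError):
    """An operation was called with arguments violating its contract."""


class InputError(TracefateError):
    """Numerically or structurally invalid user input."""


class SchemaError(InputError):
    """A table is missing required columns or rows."""
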
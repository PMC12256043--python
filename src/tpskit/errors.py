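"""Exception hierarchy.

Validation failures on user-supplied parameters raise :class:`ParameterError`,
malformed data files or tables raise :class:`InputError`, and bad pipeline or
screen configuration raises :class:`ConfigError`.  All inherit from
:class:`TPSKitError` so callers can catch the package's errors in one clause.
"""


class TPSKitError(Exception):
    """Base class for all tpskit errors."""


class ParameterError(TPSKitError, ValueError):
    """A generator or analysis parameter is out of its valid range."""


class InputError(TPSKitError, ValueError):
    """An input table, curve or record violates its contract."""


class ConfigError(TPSKitError, ValueError):
    """A configuration (screen design, pipeline config) is invalid."""


class SelectionError(TPSKitError, ValueError):
    """Component selection cannot be satisfied (e.g. too few distinct buffers)."""


class GenerationError(TPSKitError, ValueError):
    """Screen generation received an empty or incomplete selection."""
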
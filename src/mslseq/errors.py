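"""Exception types used across the package."""


class MslseqError(Exception):
    """Base class for package errors."""


class ParameterError(MslseqError, ValueError):
    """A parameter is outside its allowed range."""


class InputError(MslseqError, ValueError):
    """An input object is empty, malformed, or inconsistent."""


class StateError(MslseqError, ValueError):
    """An operation was applied to an object in the wrong state."""


class SchemaError(MslseqError, ValueError):
    """Column/variable layout of an input does not match expectations."""


class ConfigError(MslseqError, ValueError):
    """A configuration object violates its invariants."""
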
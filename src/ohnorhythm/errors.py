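"""Exception hierarchy shared across the package."""


class OhnoRhythmError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(OhnoRhythmError, ValueError):
    """A configuration object or parameter value is invalid."""


class InputError(OhnoRhythmError, ValueError):
    """Input data violate a documented precondition."""


class SchemaError(OhnoRhythmError, ValueError):
    """A required column or field is missing from a table."""


class GeneLookupError(OhnoRhythmError, KeyError):
    """A requested gene id is not present in a results store."""
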
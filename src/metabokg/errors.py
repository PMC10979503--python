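"""Exception hierarchy shared across modules."""


class MetabokgError(Exception):
    """Base class for package errors."""


class SchemaError(MetabokgError):
    """An input table is missing required columns."""


class ValidationError(MetabokgError):
    """Input values violate an invariant (duplicates, dangling references...)."""


class ParseError(MetabokgError):
    """A file could not be parsed."""


class ParameterError(MetabokgError):
    """A parameter value is outside its legal domain."""
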
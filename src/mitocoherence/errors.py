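"""Typed exceptions raised across the package."""


class MitoCoherenceError(Exception):
    """Base class for all package errors."""


class ParseError(MitoCoherenceError):
    """A tabular input file is malformed (names the offending row/column)."""


class MetadataError(MitoCoherenceError):
    """Sample annotations are missing or inconsistent."""


class CatalogError(MitoCoherenceError):
    """A gene catalog violates its structural constraints."""


class ParameterError(MitoCoherenceError):
    """A user-supplied parameter is outside its valid range."""


class DegenerateInputError(MitoCoherenceError):
    """An input is degenerate for the requested computation (e.g. zero total)."""


class ConfigError(MitoCoherenceError):
    """A simulation configuration is infeasible."""


class UndefinedCorrelationError(MitoCoherenceError):
    """A correlation is undefined (too few pairs or zero rank variance)."""
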
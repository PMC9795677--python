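"""Exception hierarchy shared across the package."""


class SynkaryoError(Exception):
    """Base class for all package errors."""


class ParseError(SynkaryoError):
    """An input file violates its format contract."""


class ValidationError(SynkaryoError):
    """Inputs are well-formed but violate a semantic invariant."""


class SaturationError(ValidationError):
    """A p-distance at or beyond 0.75, where the Jukes-Cantor correction diverges."""
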
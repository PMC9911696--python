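"""Exception hierarchy shared across the pipeline stages."""


class RnatopoError(Exception):
    """Base class for all package-specific failures."""


class ParseError(RnatopoError):
    """Malformed textual input (dot-bracket, pseudoAFM grid, profiles)."""


class PseudoknotError(ParseError):
    """Crossing base pairs; only nested secondary structures are supported."""


class GeometryError(RnatopoError):
    """Unsatisfiable spatial constraint during model building."""


class FormatError(RnatopoError):
    """Structured file does not match the expected layout."""
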
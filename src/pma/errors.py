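"""Exception hierarchy."""


class PmaError(Exception):
    """Base class for all package errors."""


class GeometryError(PmaError, ValueError):
    """Invalid or degenerate geometric input."""


class DegenerateFrameError(GeometryError):
    """Landmark vectors are (anti-)parallel; no orientation plane exists."""


class ConfigError(PmaError, ValueError):
    """Invalid run configuration."""


class FormatError(PmaError, ValueError):
    """Malformed external table or mesh file."""


class IntegrityError(PmaError, ValueError):
    """Cross-referenced ids or tables are inconsistent."""
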
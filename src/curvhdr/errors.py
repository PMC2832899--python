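"""Exception hierarchy for curvhdr.

All user-facing validation problems raise :class:`ValidationError` (or a
subclass) so the CLI can map them to exit code 2; internal invariant
violations raise plain ``RuntimeError``.
"""


class CurvHDRError(Exception):
    """Base class for all curvhdr errors."""


class ValidationError(CurvHDRError, ValueError):
    """Invalid user input: bad parameter value, malformed table, etc."""


class DegenerateChannelError(ValidationError):
    """A channel has zero variance and cannot be standardized."""


class DegenerateGeometryError(ValidationError):
    """Input points are affinely degenerate (collinear / coplanar)."""


class InsufficientDataError(ValidationError):
    """Too few events for the requested operation."""


class SpaceMismatchError(ValidationError):
    """Gate and data live in different coordinate spaces/units."""


class FormatError(CurvHDRError, ValueError):
    """A file could not be parsed (malformed FCS, bad gate JSON, ...)."""
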
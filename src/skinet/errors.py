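"""Exception hierarchy.

All errors raised by skinet derive from :class:`SkinetError`, so callers
(including the CLI, which maps them to exit code 3) can catch one type.
"""


class SkinetError(Exception):
    """Base class for all skinet errors."""


class FormatError(SkinetError, ValueError):
    """A file or in-memory structure violates the expected format."""


class DegenerateInputError(SkinetError, ValueError):
    """Input is structurally valid but degenerate (e.g. zero-variance spectrum)."""


class DimensionError(SkinetError, ValueError):
    """Vector lengths or grid dimensions are inconsistent."""


class BoundsError(SkinetError, ValueError):
    """A coordinate or schedule step is outside its valid range."""
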
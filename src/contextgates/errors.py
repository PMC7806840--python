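"""Exception hierarchy for the pipeline.

Argument misuse raises plain :class:`ValueError`; problems rooted in the
data itself (too few events, unusable controls, non-positive values where a
log is needed) raise :class:`DataError`; file-format problems raise
:class:`FormatError`.
"""


class ContextGatesError(Exception):
    """Base class for package-specific errors."""


class DataError(ContextGatesError, ValueError):
    """The supplied data cannot support the requested computation."""


class FormatError(ContextGatesError, ValueError):
    """A file or table does not conform to the expected format."""
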
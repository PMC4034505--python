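"""Exception hierarchy shared across the package."""


class RAAindexError(Exception):
    """Base class for all package-specific errors."""


class AAindexParseError(RAAindexError):
    """Malformed AAindex flat-file record."""


class EmptyTableError(RAAindexError):
    """An operation produced or received a property table with no properties."""


class DegenerateLabelsError(RAAindexError):
    """Hydropathy labels contain only one class; classification is undefined."""


class EmptySelectionError(RAAindexError):
    """Nested selection rejected even the single best-ranked property."""

    def __init__(self, message: str, step_errors=None):
        super().__init__(message)
        self.step_errors = step_errors


class EncodingError(RAAindexError):
    """A sequence contains a residue the coding scheme cannot represent."""


class EmptyBlockError(RAAindexError):
    """Gap-column removal left no alignment columns."""


class DegenerateMatrixError(RAAindexError):
    """PCA input has no usable variance (or fewer than two rows)."""
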